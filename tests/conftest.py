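import numpy as np
import pandas as pd
import pytest

from methencroach import GenomeLayout, MethylationTrack
from methencroach.synthetic import MethylomeSimConfig, simulate_methylome


def make_track(records, name="sample"):
    """Build a track from (chrom, pos, meth, cov) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "meth", "cov"])
    df["strand"] = "+"
    return MethylationTrack(df, name=name)


@pytest.fixture(scope="session")
def small_genome():
    return GenomeLayout((("chr1", 100_000), ("chr2", 50_000)))


@pytest.fixture(scope="session")
def default_simulation():
    """One full-size synthetic methylome shared by the slower tests."""
    cfg = MethylomeSimConfig(seed=11)
    genome, cgis, genes, tracks, truth = simulate_methylome(cfg)
    wt = [tracks[k] for k in tracks if k.startswith("WT")]
    ko = [tracks[k] for k in tracks if k.startswith("KO")]
    return {"config": cfg, "genome": genome, "cgis": cgis, "genes": genes,
            "tracks": tracks, "wt": wt, "ko": ko, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(7)
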