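"""Synthetic two-condition WGBS and ChIP-seq inputs with ground truth.

The methylome generator emulates the statistical structure the
encroachment detector assumes: CpG-dense islands that are unmethylated
in the wild type and, in the knockout, gain methylation invading from
the 5' end, the 3' end, both ends, or across the whole island.  Per
CpG and sample, coverage is Poisson and the methylated-read count is
binomial in that coverage — the sampling model of bisulfite read
counts at a site with a fixed underlying methylation level.

The peak generator emulates replicate narrowPeak tiers (high-confidence
and relaxed "FDR50") plus per-sample fragment BEDs: true peaks appear
in every replicate's FDR50 set, decoys in exactly one, and fragment
counts per peak are Poisson with a planted occupancy fold-change
between conditions.

Every draw comes from a dedicated RNG stream keyed by (seed, sample,
chromosome), so adding replicates or chromosomes never perturbs the
data already generated for the existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeLayout,
    GenomicInterval,
    MethylationTrack,
    NarrowPeakRecord,
    write_bed,
    write_chrom_sizes,
    write_methratio,
    write_narrowpeak,
    write_table,
)
from .annotation import GeneModel, write_genes_tsv

ENCROACHMENT_CLASSES = ("none", "5prime", "bidirectional", "3prime", "full")


@dataclass
class MethylomeSimConfig:
    """Parameters of the synthetic two-condition methylome.

    Defaults describe the standard recovery experiment: 260 islands —
    20 each with 5', bidirectional and 3' encroachment planted at
    depth 0.5 over half the island, plus 200 unaffected islands — at
    30x mean coverage with two replicates per condition.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 700_000
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "none": 200, "5prime": 20, "bidirectional": 20, "3prime": 20, "full": 0,
        }
    )
    cgi_length_range: tuple[int, int] = (600, 1200)
    cgi_min_gap: int = 2_500
    cpg_spacing_cgi: int = 10
    cpg_spacing_background: int = 150
    baseline_cgi: float = 0.05
    baseline_background: float = 0.8
    mean_coverage: float = 30.0
    n_replicates: int = 2
    delta: float = 0.5
    extent: float = 0.5
    gene_fraction: float = 0.5
    gene_length: int = 10_000

    @property
    def n_cgis(self) -> int:
        return sum(self.class_counts.values())

    @property
    def class_proportions(self) -> dict[str, float]:
        n = self.n_cgis
        return {k: v / n for k, v in self.class_counts.items()}

    def validate(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if not 0.0 < self.extent <= 1.0:
            raise ValueError("extent must be in (0, 1]")
        for p in (self.baseline_cgi, self.baseline_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("baseline methylation levels must be in [0, 1]")
        unknown = set(self.class_counts) - set(ENCROACHMENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown encroachment classes: {sorted(unknown)}")
        if self.n_cgis < 1:
            raise ValueError("need at least one CGI")
        if self.n_replicates < 1 or self.n_chromosomes < 1:
            raise ValueError("need >=1 replicate and >=1 chromosome")
        if self.mean_coverage <= 0:
            raise ValueError("mean coverage must be positive")


@dataclass
class PeakSimConfig:
    """Parameters of the synthetic replicate peak / fragment sets."""

    seed: int = 0
    chromosome_length: int = 1_000_000
    n_peaks: int = 60
    peak_length: int = 500
    peak_gap: int = 5_000
    n_decoys_per_replicate: int = 10
    fragments_per_peak: float = 200.0
    fragment_length: int = 200
    background_fragments: int = 2_000
    n_replicates: int = 2
    fold_change: float = 4.0
    fraction_up: float = 0.25
    fraction_down: float = 0.25

    def validate(self) -> None:
        if self.n_peaks < 1:
            raise ValueError("need >=1 peak")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        if self.fraction_up + self.fraction_down > 1.0:
            raise ValueError("fraction_up + fraction_down must be <= 1")
        if (self.peak_length + self.peak_gap) * (self.n_peaks + 2) > self.chromosome_length:
            raise ValueError("peaks do not fit on the chromosome")


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, *key))))


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def _place_cgis(config: MethylomeSimConfig, genome: GenomeLayout,
                rng: np.random.Generator) -> list[GenomicInterval]:
    lo, hi = config.cgi_length_range
    per_chrom = -(-config.n_cgis // config.n_chromosomes)  # ceil division
    if per_chrom * (hi + config.cgi_min_gap) + hi > config.chromosome_length:
        raise ValueError(
            f"cannot fit {per_chrom} CGIs of <= {hi} bp on a "
            f"{config.chromosome_length} bp chromosome"
        )
    cgis: list[GenomicInterval] = []
    idx = 0
    for chrom, length in genome:
        cursor = config.cgi_min_gap
        for _ in range(per_chrom):
            if idx >= config.n_cgis:
                break
            cgi_len = int(rng.integers(lo, hi + 1))
            jitter = int(rng.integers(0, config.cgi_min_gap // 2 + 1))
            start = cursor + jitter
            if start + cgi_len + config.cgi_min_gap > length:
                break
            idx += 1
            cgis.append(GenomicInterval(chrom, start, start + cgi_len, f"CGI_{idx:04d}"))
            cursor = start + cgi_len + config.cgi_min_gap
    if idx < config.n_cgis:
        raise ValueError(f"placed only {idx} of {config.n_cgis} CGIs; enlarge the genome")
    return cgis


def _assign_classes(config: MethylomeSimConfig, cgis: list[GenomicInterval],
                    rng: np.random.Generator) -> list[str]:
    labels: list[str] = []
    for cls in ENCROACHMENT_CLASSES:
        labels.extend([cls] * config.class_counts.get(cls, 0))
    order = rng.permutation(len(cgis))
    assigned = [""] * len(cgis)
    for label, pos in zip(labels, order):
        assigned[pos] = label
    return assigned


def _site_methylation(config: MethylomeSimConfig, positions: np.ndarray,
                      cgi: GenomicInterval, cls: str) -> np.ndarray:
    """Underlying KO methylation level at each CpG of one island.

    The encroachment front is a linear ramp: depth ``delta`` at the
    affected island edge decaying to zero at ``extent * length`` into
    the island.  Bidirectional islands take the deeper of the two ramps;
    ``full`` raises the whole island uniformly.
    """
    p = np.full(positions.shape, config.baseline_cgi)
    if cls == "none":
        return p
    length = cgi.end - cgi.start
    span = config.extent * length
    d_left = positions - cgi.start
    d_right = cgi.end - 1 - positions
    ramp_left = np.clip(1.0 - d_left / span, 0.0, 1.0)
    ramp_right = np.clip(1.0 - d_right / span, 0.0, 1.0)
    if cls == "5prime":
        bump = ramp_left
    elif cls == "3prime":
        bump = ramp_right
    elif cls == "bidirectional":
        bump = np.maximum(ramp_left, ramp_right)
    elif cls == "full":
        bump = np.ones_like(p)
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(f"unknown class {cls!r}")
    return np.clip(p + config.delta * bump, 0.0, 1.0)


def simulate_methylome(config: MethylomeSimConfig):
    """Generate the full WGBS input set with ground-truth labels.

    Returns ``(genome, cgis, genes, tracks, ground_truth)`` where
    ``tracks`` maps sample names (``WT_rep1`` ... ``KO_repN``) to
    :class:`MethylationTrack` and ``ground_truth`` is a per-CGI
    DataFrame with the planted class and affected segment range.
    Deterministic given ``config.seed``.
    """
    config.validate()
    genome = GenomeLayout(
        tuple((f"chr{i + 1}", config.chromosome_length) for i in range(config.n_chromosomes))
    )
    layout_rng = _stream(config.seed, 0, 0)
    cgis = _place_cgis(config, genome, layout_rng)
    classes = _assign_classes(config, cgis, layout_rng)

    # CpG positions and underlying per-condition methylation, per chromosome
    chrom_sites: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    truth_rows = []
    genes: list[GeneModel] = []
    for ci, (chrom, length) in enumerate(genome):
        chrom_cgis = [(iv, cls) for iv, cls in zip(cgis, classes) if iv.chrom == chrom]
        pos_parts, p_wt_parts, p_ko_parts = [], [], []
        cursor = 0
        for iv, cls in chrom_cgis:
            bg = np.arange(cursor, iv.start, config.cpg_spacing_background)
            pos_parts.append(bg)
            p_wt_parts.append(np.full(bg.shape, config.baseline_background))
            p_ko_parts.append(np.full(bg.shape, config.baseline_background))
            inside = np.arange(iv.start, iv.end, config.cpg_spacing_cgi)
            pos_parts.append(inside)
            p_wt_parts.append(np.full(inside.shape, config.baseline_cgi))
            p_ko_parts.append(_site_methylation(config, inside, iv, cls))
            cursor = iv.end
        tail = np.arange(cursor, length, config.cpg_spacing_background)
        pos_parts.append(tail)
        p_wt_parts.append(np.full(tail.shape, config.baseline_background))
        p_ko_parts.append(np.full(tail.shape, config.baseline_background))
        chrom_sites[chrom] = (
            np.concatenate(pos_parts),
            np.concatenate(p_wt_parts),
            np.concatenate(p_ko_parts),
        )
        # one gene per selected CGI: TSS at the island start, alternating strand
        gene_rng = _stream(config.seed, 1, ci)
        for iv, cls in chrom_cgis:
            if gene_rng.random() >= config.gene_fraction:
                continue
            strand = "+" if gene_rng.random() < 0.5 else "-"
            if strand == "+":
                tss = iv.start
                tes = min(tss + config.gene_length, length)
            else:
                tss = iv.end
                tes = max(tss - config.gene_length, 1)
            if tss == tes:
                continue
            lo, hi = min(tss, tes), max(tss, tes)
            mid = (lo + hi) // 2
            exons = ((lo, min(lo + 300, hi)), (max(mid, lo + 300), min(mid + 300, hi)))
            exons = tuple((a, b) for a, b in exons if a < b)
            genes.append(GeneModel(f"gene_{iv.name}", iv.chrom, strand, tss, tes, exons))

    for iv, cls in zip(cgis, classes):
        length = iv.end - iv.start
        span = int(round(config.extent * length))
        if cls == "5prime":
            aff = (iv.start, iv.start + span)
        elif cls == "3prime":
            aff = (iv.end - span, iv.end)
        elif cls == "bidirectional":
            aff = (iv.start, iv.end)  # both edges; centre untouched when extent < 0.5
        elif cls == "full":
            aff = (iv.start, iv.end)
        else:
            aff = (-1, -1)
        truth_rows.append(
            {
                "name": iv.name, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "class": cls, "affected_start": aff[0], "affected_end": aff[1],
            }
        )
    ground_truth = pd.DataFrame(truth_rows)

    samples = [f"WT_rep{r + 1}" for r in range(config.n_replicates)] + [
        f"KO_rep{r + 1}" for r in range(config.n_replicates)
    ]
    tracks: dict[str, MethylationTrack] = {}
    for si, sample in enumerate(samples):
        is_ko = sample.startswith("KO")
        parts = []
        for ci, (chrom, _) in enumerate(genome):
            pos, p_wt, p_ko = chrom_sites[chrom]
            p = p_ko if is_ko else p_wt
            rng = _stream(config.seed, 2, si, ci)
            cov = rng.poisson(config.mean_coverage, size=pos.shape)
            keep = cov > 0
            meth = rng.binomial(cov[keep], p[keep])
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[keep],
                        "strand": "+",
                        "meth": meth,
                        "cov": cov[keep],
                    }
                )
            )
        tracks[sample] = MethylationTrack(pd.concat(parts, ignore_index=True), name=sample)
    return genome, cgis, genes, tracks, ground_truth


# ---------------------------------------------------------------------------
# peak / fragment sets
# ---------------------------------------------------------------------------


def _peak_record(chrom, start, end, name, q=2.0) -> NarrowPeakRecord:
    return NarrowPeakRecord(chrom, start, end, name, 100, ".", 5.0, q + 1.0, q,
                            (end - start) // 2)


def simulate_peaksets(config: PeakSimConfig):
    """Generate replicate peak tiers, fragment BEDs and ground truth.

    Returns ``(genome, peak_tiers, fragments, ground_truth)``:

    * ``peak_tiers[condition][replicate]`` is a dict with keys
      ``"high"`` and ``"fdr50"`` holding :class:`NarrowPeakRecord`
      lists; true peaks are present in every replicate's FDR50 set,
      decoys in exactly one replicate.
    * ``fragments[sample]`` is a DataFrame (chrom/start/end) of
      fragment intervals; fragment counts per peak are Poisson with
      the planted fold-change between KO and WT.
    * ``ground_truth`` is per-peak: planted fold-change and direction.
    """
    config.validate()
    chrom = "chr1"
    genome = GenomeLayout(((chrom, config.chromosome_length),))
    rng = _stream(config.seed, 10, 0)

    pitch = config.peak_length + config.peak_gap
    starts = config.peak_gap + pitch * np.arange(config.n_peaks)
    peaks = [
        GenomicInterval(chrom, int(s), int(s) + config.peak_length, f"peak_{i + 1:03d}")
        for i, s in enumerate(starts)
    ]

    n_up = int(round(config.fraction_up * config.n_peaks))
    n_down = int(round(config.fraction_down * config.n_peaks))
    directions = np.array(
        ["up"] * n_up + ["down"] * n_down + ["none"] * (config.n_peaks - n_up - n_down)
    )
    rng.shuffle(directions)
    fold = np.where(
        directions == "up", config.fold_change,
        np.where(directions == "down", 1.0 / config.fold_change, 1.0),
    )
    ground_truth = pd.DataFrame(
        {
            "name": [p.name for p in peaks],
            "chrom": chrom,
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "fold_change": fold,
            "direction": directions,
        }
    )

    # decoy regions beyond the true peaks, one private block per replicate
    decoy_base = int(starts[-1] + pitch)
    peak_tiers: dict[str, list[dict[str, list[NarrowPeakRecord]]]] = {}
    fragments: dict[str, pd.DataFrame] = {}
    for cond_i, cond in enumerate(("WT", "KO")):
        peak_tiers[cond] = []
        for rep in range(config.n_replicates):
            srng = _stream(config.seed, 11, cond_i, rep)
            fdr50 = [
                _peak_record(p.chrom,
                             max(0, p.start - int(srng.integers(0, 50))),
                             p.end + int(srng.integers(0, 50)),
                             f"{cond}_r{rep + 1}_{p.name}", q=1.0)
                for p in peaks
            ]
            high = [
                _peak_record(p.chrom, p.start, p.end, f"{cond}_r{rep + 1}_{p.name}_hc", q=3.0)
                for p in peaks
            ]
            for d in range(config.n_decoys_per_replicate):
                s = decoy_base + pitch * (d + config.n_decoys_per_replicate
                                          * (rep + config.n_replicates * cond_i))
                if s + config.peak_length > config.chromosome_length:
                    raise ValueError("decoy peaks exceed chromosome; enlarge the genome")
                fdr50.append(
                    _peak_record(chrom, s, s + config.peak_length,
                                 f"{cond}_r{rep + 1}_decoy_{d + 1}", q=0.5)
                )
            peak_tiers[cond].append({"high": high, "fdr50": fdr50})

            # fragments: per true peak Poisson(lambda * fc if KO), plus noise
            frag_rows = []
            lam = config.fragments_per_peak * (fold if cond == "KO" else np.ones_like(fold))
            counts = srng.poisson(lam)
            for p, c in zip(peaks, counts):
                if c == 0:
                    continue
                centers = srng.integers(p.start, p.end, size=c)
                fs = np.maximum(centers - config.fragment_length // 2, 0)
                frag_rows.append(pd.DataFrame({"chrom": p.chrom, "start": fs,
                                               "end": fs + config.fragment_length}))
            noise_starts = srng.integers(
                0, config.chromosome_length - config.fragment_length,
                size=config.background_fragments,
            )
            frag_rows.append(pd.DataFrame({"chrom": chrom, "start": noise_starts,
                                           "end": noise_starts + config.fragment_length}))
            frag = pd.concat(frag_rows, ignore_index=True).sort_values(
                ["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
            fragments[f"{cond}_rep{rep + 1}"] = frag
    return genome, peak_tiers, fragments, ground_truth


# ---------------------------------------------------------------------------
# on-disk datasets (the file dialects the pipeline reads)
# ---------------------------------------------------------------------------


def write_methylome_dataset(config: MethylomeSimConfig, outdir) -> dict[str, str]:
    """Simulate a methylome and write every pipeline input file.

    Emits chrom.sizes, cgis.bed, genes.tsv, one methratio TSV per
    sample and ground_truth.tsv; returns the path map.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, cgis, genes, tracks, truth = simulate_methylome(config)
    paths = {"chrom_sizes": str(outdir / "chrom.sizes"),
             "cgi_table": str(outdir / "cgis.bed"),
             "genes": str(outdir / "genes.tsv"),
             "ground_truth": str(outdir / "ground_truth.tsv")}
    write_chrom_sizes(genome, paths["chrom_sizes"])
    write_bed(cgis, paths["cgi_table"], genome)
    write_genes_tsv(genes, paths["genes"])
    write_table(truth, paths["ground_truth"])
    paths["wt_methratio"] = []
    paths["ko_methratio"] = []
    for name, track in tracks.items():
        p = str(outdir / f"{name}.methratio")
        write_methratio(track, p)
        paths["ko_methratio" if name.startswith("KO") else "wt_methratio"].append(p)
    return paths


def write_peak_dataset(config: PeakSimConfig, outdir, antibody: str = "target") -> dict:
    """Simulate replicate peak/fragment sets and write them to disk.

    Emits per condition and replicate a high-confidence and an FDR50
    narrowPeak file plus a fragment BED, and ground_truth_peaks.tsv;
    returns a path map shaped like a PipelineConfig antibody block.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, peak_tiers, fragments, truth = simulate_peaksets(config)
    write_chrom_sizes(genome, outdir / "chrom.sizes")
    write_table(truth, outdir / "ground_truth_peaks.tsv")
    block = {"name": antibody, "wt": {}, "ko": {}}
    for cond_key, cond in (("wt", "WT"), ("ko", "KO")):
        highs, fdr50s, frags = [], [], []
        for rep, tiers in enumerate(peak_tiers[cond]):
            hp = outdir / f"{cond}_rep{rep + 1}_high.narrowPeak"
            fp = outdir / f"{cond}_rep{rep + 1}_fdr50.narrowPeak"
            write_narrowpeak(tiers["high"], hp)
            write_narrowpeak(tiers["fdr50"], fp)
            highs.append(str(hp))
            fdr50s.append(str(fp))
            frag = fragments[f"{cond}_rep{rep + 1}"]
            bp = outdir / f"{cond}_rep{rep + 1}_fragments.bed"
            ivs = [GenomicInterval(c, int(s), int(e), f"frag_{i + 1}")
                   for i, (c, s, e) in enumerate(zip(frag["chrom"], frag["start"],
                                                     frag["end"]))]
            write_bed(ivs, bp, genome)
            frags.append(str(bp))
        block[cond_key] = {"high": highs, "fdr50": fdr50s, "fragments": frags}
    return {"chrom_sizes": str(outdir / "chrom.sizes"),
            "ground_truth": str(outdir / "ground_truth_peaks.tsv"),
            "antibody": block}
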