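"""Coverage filtering and differential methylation calling.

A differentially methylated cytosine (DMC) is a CpG whose pooled
knockout-vs-wild-type 2x2 read-count table is significant after
Benjamini-Hochberg correction (q <= 0.05 by default) *and* whose
methylation difference exceeds 25 percentage points.  The same test
and thresholds, applied to read counts summed over all covered CpGs
inside a region, yield differentially methylated regions (DMRs) for
any predefined region family: CpG islands, their 2-kbp shores,
promoters (TSS +/- 2 kbp) and 100/500/1000-bp windows sliding by half
their length.

The per-site test is a two-sided Fisher's exact test on the pooled
condition counts.  Replicates are pooled by summing counts, so the
test is order-invariant across replicates; a replicate-aware model
(e.g. logistic regression with overdispersion) is a possible extension
but is not implemented here.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeLayout, GenomicInterval, MethylationTrack
from .annotation import GeneModel

logger = logging.getLogger(__name__)

WINDOW_SIZES = (100, 500, 1_000)


def _as_track_list(tracks) -> list[MethylationTrack]:
    if isinstance(tracks, Mapping):
        return list(tracks.values())
    if isinstance(tracks, MethylationTrack):
        return [tracks]
    return list(tracks)


# ---------------------------------------------------------------------------
# coverage filtering
# ---------------------------------------------------------------------------


def filter_by_coverage(tracks, min_cov: int, scope: str = "all_samples"):
    """Drop CpG sites that do not meet the coverage threshold.

    ``scope="all_samples"``: a site survives only if it is present with
    coverage >= ``min_cov`` in *every* track (a site absent from a
    track counts as coverage 0 and is dropped everywhere).
    ``scope="per_replicate"``: each track is filtered on its own
    coverage only; no cross-sample intersection.

    Returns tracks in the same container shape as the input (mapping
    in, mapping out).
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if scope not in {"all_samples", "per_replicate"}:
        raise ValueError(f"unknown scope {scope!r}")
    track_list = _as_track_list(tracks)
    if not track_list:
        raise ValueError("need at least one track")

    if scope == "per_replicate":
        filtered = [
            MethylationTrack(t.df[t.df["cov"] >= min_cov], name=t.name) for t in track_list
        ]
    else:
        keys = None
        for t in track_list:
            ok = t.df.loc[t.df["cov"] >= min_cov, ["chrom", "pos"]]
            idx = pd.MultiIndex.from_frame(ok)
            keys = idx if keys is None else keys.intersection(idx)
        filtered = []
        for t in track_list:
            site_idx = pd.MultiIndex.from_frame(t.df[["chrom", "pos"]])
            filtered.append(MethylationTrack(t.df[site_idx.isin(keys)], name=t.name))

    if isinstance(tracks, Mapping):
        return dict(zip(tracks.keys(), filtered))
    if isinstance(tracks, MethylationTrack):
        return filtered[0]
    return filtered


def pool_counts(tracks) -> pd.DataFrame:
    """Sum methylated/total read counts per CpG site across tracks."""
    track_list = _as_track_list(tracks)
    cat = pd.concat([t.df[["chrom", "pos", "meth", "cov"]] for t in track_list],
                    ignore_index=True)
    pooled = cat.groupby(["chrom", "pos"], as_index=False, sort=True).sum()
    return pooled


# ---------------------------------------------------------------------------
# the per-table test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=200_000)
def _fisher_two_sided(meth_ko: int, unmeth_ko: int, meth_wt: int, unmeth_wt: int) -> float:
    return float(
        stats.fisher_exact([[meth_ko, unmeth_ko], [meth_wt, unmeth_wt]],
                           alternative="two-sided")[1]
    )


def _test_tables(meth_wt, cov_wt, meth_ko, cov_ko) -> np.ndarray:
    p = np.empty(len(meth_wt))
    for i, (mw, cw, mk, ck) in enumerate(zip(meth_wt, cov_wt, meth_ko, cov_ko)):
        p[i] = _fisher_two_sided(int(mk), int(ck - mk), int(mw), int(cw - mw))
    return p


def _finalize_calls(df: pd.DataFrame, min_diff: float, fdr: float) -> pd.DataFrame:
    """Shared tail of DMC/DMR calling: difference, BH, thresholds."""
    df = df.copy()
    df["mean_wt"] = df["meth_wt"] / df["cov_wt"]
    df["mean_ko"] = df["meth_ko"] / df["cov_ko"]
    df["diff_pp"] = 100.0 * (df["mean_ko"] - df["mean_wt"])
    df["p"] = _test_tables(df["meth_wt"], df["cov_wt"], df["meth_ko"], df["cov_ko"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    df["status"] = np.where(df["diff_pp"] > 0, "hyper", "hypo")
    df["significant"] = (df["q"] <= fdr) & (df["diff_pp"].abs() >= min_diff)
    return df


def call_dmc(
    wt_tracks,
    ko_tracks,
    *,
    min_diff: float = 25.0,
    fdr: float = 0.05,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Call differentially methylated cytosines between KO and WT.

    Sites are restricted to those with coverage >= ``min_cov`` in all
    samples of both conditions; replicate counts are pooled per
    condition and each CpG tested with a two-sided Fisher's exact
    test, BH-corrected over all tested CpGs.  ``diff_pp`` is the
    KO - WT methylation difference in percentage points; a CpG is a
    DMC (``significant``) when ``q <= fdr`` and ``|diff_pp| >=
    min_diff``.  Returns the full tested table; filter on
    ``significant`` for the DMC set.
    """
    wt = _as_track_list(wt_tracks)
    ko = _as_track_list(ko_tracks)
    if not wt or not ko:
        raise ValueError("need >=1 replicate per condition")
    all_f = filter_by_coverage(wt + ko, min_cov, scope="all_samples")
    wt_f, ko_f = all_f[: len(wt)], all_f[len(wt):]
    pooled_wt = pool_counts(wt_f).rename(columns={"meth": "meth_wt", "cov": "cov_wt"})
    pooled_ko = pool_counts(ko_f).rename(columns={"meth": "meth_ko", "cov": "cov_ko"})
    merged = pooled_wt.merge(pooled_ko, on=["chrom", "pos"], how="inner")
    if merged.empty:
        logger.warning("no CpG passed the coverage filter; empty DMC table")
        return pd.DataFrame(
            columns=["chrom", "pos", "meth_wt", "cov_wt", "meth_ko", "cov_ko",
                     "mean_wt", "mean_ko", "diff_pp", "p", "q", "status", "significant"]
        )
    return _finalize_calls(merged, min_diff, fdr)


def call_dmr(
    regions: Sequence[GenomicInterval],
    wt_tracks,
    ko_tracks,
    *,
    min_diff: float = 25.0,
    fdr: float = 0.05,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Differential methylation over predefined regions.

    For each region, methylated/total counts of all coverage-surviving
    CpGs inside it are summed per condition and the DMC test and
    thresholds applied to the region-level table.  Regions containing
    no surviving CpG are reported with ``status="untested"`` and NaN
    statistics.
    """
    if not len(regions):
        raise ValueError("region set is empty")
    wt = _as_track_list(wt_tracks)
    ko = _as_track_list(ko_tracks)
    all_f = filter_by_coverage(wt + ko, min_cov, scope="all_samples")
    wt_f, ko_f = all_f[: len(wt)], all_f[len(wt):]
    pooled_wt = pool_counts(wt_f)
    pooled_ko = pool_counts(ko_f)
    sites = pooled_wt.merge(pooled_ko, on=["chrom", "pos"], suffixes=("_wt", "_ko"))

    # per-chromosome prefix sums over position-sorted surviving sites
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        by_chrom[chrom] = (
            pos,
            np.concatenate([[0], np.cumsum(sub["meth_wt"].to_numpy())]),
            np.concatenate([[0], np.cumsum(sub["cov_wt"].to_numpy())]),
            np.concatenate([[0], np.cumsum(sub["meth_ko"].to_numpy())]),
            np.concatenate([[0], np.cumsum(sub["cov_ko"].to_numpy())]),
        )

    rows = []
    for iv in regions:
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            rows.append((iv.chrom, iv.start, iv.end, iv.name, 0, 0, 0, 0, 0))
            continue
        pos, cmw, ccw, cmk, cck = entry
        lo = int(np.searchsorted(pos, iv.start, side="left"))
        hi = int(np.searchsorted(pos, iv.end, side="left"))
        rows.append(
            (iv.chrom, iv.start, iv.end, iv.name, hi - lo,
             int(cmw[hi] - cmw[lo]), int(ccw[hi] - ccw[lo]),
             int(cmk[hi] - cmk[lo]), int(cck[hi] - cck[lo]))
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "n_cpg",
                 "meth_wt", "cov_wt", "meth_ko", "cov_ko"],
    )
    tested = table[table["n_cpg"] > 0].copy()
    untested = table[table["n_cpg"] == 0].copy()
    if len(tested):
        tested = _finalize_calls(tested, min_diff, fdr)
    for col in ("mean_wt", "mean_ko", "diff_pp", "p", "q"):
        untested[col] = np.nan
    untested["status"] = "untested"
    untested["significant"] = False
    out = pd.concat([tested, untested], ignore_index=True)
    return out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# region families
# ---------------------------------------------------------------------------


def sliding_windows(genome: GenomeLayout, size: int) -> list[GenomicInterval]:
    """Windows of ``size`` bp sliding by ``size // 2``, fully inside bounds."""
    step = size // 2
    out = []
    for chrom, length in genome:
        n = 0
        for start in range(0, length - size + 1, step):
            n += 1
            out.append(GenomicInterval(chrom, start, start + size, f"{chrom}_w{size}_{n}"))
    return out


def cgi_shores(
    cgis: Sequence[GenomicInterval], genome: GenomeLayout, width: int = 2_000
) -> list[GenomicInterval]:
    """2-kbp flanks of each CGI, clipped at chromosome ends and truncated
    where they would re-enter a neighbouring CGI."""
    out = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in cgis:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, items in by_chrom.items():
        items = sorted(items, key=lambda iv: iv.start)
        length = genome.length_of(chrom)
        for i, iv in enumerate(items):
            prev_end = items[i - 1].end if i > 0 else 0
            next_start = items[i + 1].start if i + 1 < len(items) else length
            left = (max(0, iv.start - width, prev_end), iv.start)
            right = (iv.end, min(length, iv.end + width, next_start))
            if left[0] < left[1]:
                out.append(GenomicInterval(chrom, left[0], left[1], f"{iv.name}_shoreL"))
            if right[0] < right[1]:
                out.append(GenomicInterval(chrom, right[0], right[1], f"{iv.name}_shoreR"))
    return out


def promoters(
    genes: Sequence[GeneModel], genome: GenomeLayout, flank: int = 2_000
) -> list[GenomicInterval]:
    """TSS +/- ``flank`` windows (strand determines where the TSS is)."""
    out = []
    for g in genes:
        length = genome.length_of(g.chrom)
        start, end = max(0, g.tss - flank), min(length, g.tss + flank)
        if start < end:
            out.append(GenomicInterval(g.chrom, start, end, f"{g.name}_promoter", g.strand))
    return out


def make_region_families(
    genome: GenomeLayout,
    cgis: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    *,
    shore_width: int = 2_000,
    promoter_flank: int = 2_000,
    window_sizes: Sequence[int] = WINDOW_SIZES,
) -> dict[str, list[GenomicInterval]]:
    """The standard DMR region families, all clipped to chromosome bounds."""
    families: dict[str, list[GenomicInterval]] = {
        "CGI": list(cgis),
        "CGI_shore": cgi_shores(cgis, genome, shore_width),
        "promoter": promoters(genes, genome, promoter_flank),
    }
    for size in window_sizes:
        families[f"window{size}"] = sliding_windows(genome, size)
    return families
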