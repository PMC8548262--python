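"""Detection of DNA-hypermethylation encroachment into CpG islands.

The detector compares knockout (KO) and wild-type (WT) CpG methylation
tracks and finds islands that gain methylation from their 5' end, from
their 3' end, from both ends, or centrally.  The procedure:

1. Keep CpGs covered by >= 4 reads in every replicate of both
   conditions; per condition, a CpG's level is the mean of its
   replicate ratios.
2. Tile the genome into fixed 40-bp bins anchored at coordinate 0;
   each bin carries the mean level of its CpGs per condition and the
   difference ``diff = KO - WT`` (NaN when either side has no CpG).
3. Prefilter: an island is a candidate if it overlaps >= 4 non-NaN
   bins with ``diff >= 0.25``, at least one of which has
   ``diff >= 0.50``.
4. Candidates are re-profiled at CpG (not bin) resolution: each
   island, regardless of length, is split into 40 equal segments;
   a segment's value is the mean level of the CpGs falling into it,
   NaN when empty.
5. The per-segment KO - WT difference matrix keeps islands with at
   most 30 NaN cells; rows are scored by the NaN-ignoring means of
   segments 1-10 (5' end), 11-30 (central) and 31-40 (3' end), each
   score ranked in descending order, and the union of the top 250 per
   ranking is reported.

Sign convention: ``diff = KO - WT`` everywhere, so hypermethylation in
the knockout is positive and "top" of a descending ranking means
strongest encroachment.  5'/3' refer to the genomic left/right ends of
the island, not to any hosting gene's strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeLayout, GenomicInterval, MethylationTrack
from .methylation import _as_track_list, filter_by_coverage

logger = logging.getLogger(__name__)

CLASS_OF_RANKING = {"5prime": "5prime", "central": "bidirectional", "3prime": "3prime"}
RANKINGS = ("5prime", "central", "3prime")


@dataclass
class BinnedDiffTrack:
    """Fixed-width genome bins with per-condition means and KO-WT diff.

    ``data[chrom]`` holds three equal-length float arrays (wt, ko,
    diff) covering the chromosome from coordinate 0; entries are NaN
    where no qualifying CpG falls in the bin.  ``diff`` is NaN iff
    either condition mean is NaN.
    """

    bin_width: int
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def diffs_overlapping(self, iv: GenomicInterval) -> np.ndarray:
        """diff values of every bin sharing >= 1 bp with the interval."""
        wt, ko, diff = self.data[iv.chrom]
        first = iv.start // self.bin_width
        last = (iv.end - 1) // self.bin_width  # inclusive
        return diff[first: last + 1]


def qualifying_cpg_ratios(
    wt_tracks, ko_tracks, *, min_cov: int = 4, combine: str = "mean_ratio"
) -> pd.DataFrame:
    """Per-condition CpG methylation levels over the qualifying sites.

    A CpG qualifies iff its coverage is >= ``min_cov`` in *every*
    replicate of *both* conditions.  Per condition the level is the
    unweighted mean of replicate ratios (``combine="mean_ratio"``) or
    the pooled-count ratio (``combine="pooled"``).

    Returns a DataFrame with columns chrom, pos, wt, ko sorted by
    position.
    """
    if combine not in {"mean_ratio", "pooled"}:
        raise ValueError(f"unknown combine mode {combine!r}")
    wt = _as_track_list(wt_tracks)
    ko = _as_track_list(ko_tracks)
    if not wt or not ko:
        raise ValueError("need >=1 replicate per condition")
    filtered = filter_by_coverage(wt + ko, min_cov, scope="all_samples")
    wt_f, ko_f = filtered[: len(wt)], filtered[len(wt):]

    def condition_level(tracks: list[MethylationTrack]) -> pd.Series:
        frames = [t.df.set_index(["chrom", "pos"]) for t in tracks]
        if combine == "mean_ratio":
            ratios = pd.concat([f["ratio"] for f in frames], axis=1)
            return ratios.mean(axis=1)
        meth = sum(f["meth"] for f in frames)
        cov = sum(f["cov"] for f in frames)
        return meth / cov

    out = pd.DataFrame({"wt": condition_level(wt_f), "ko": condition_level(ko_f)})
    out = out.reset_index().sort_values(["chrom", "pos"], kind="mergesort")
    return out.reset_index(drop=True)


def bin_methylation(
    wt_tracks,
    ko_tracks,
    genome: GenomeLayout,
    *,
    bin_width: int = 40,
    min_cov: int = 4,
    combine: str = "mean_ratio",
) -> BinnedDiffTrack:
    """Average qualifying-CpG methylation into fixed-width genome bins."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    sites = qualifying_cpg_ratios(wt_tracks, ko_tracks, min_cov=min_cov, combine=combine)
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, length in genome:
        n_bins = -(-length // bin_width)
        sub = sites[sites["chrom"] == chrom]
        idx = (sub["pos"].to_numpy() // bin_width).astype(np.int64)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        wt_sum = np.bincount(idx, weights=sub["wt"].to_numpy(), minlength=n_bins)
        ko_sum = np.bincount(idx, weights=sub["ko"].to_numpy(), minlength=n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            wt_mean = np.where(counts > 0, wt_sum / counts, np.nan)
            ko_mean = np.where(counts > 0, ko_sum / counts, np.nan)
        data[chrom] = (wt_mean, ko_mean, ko_mean - wt_mean)
    return BinnedDiffTrack(bin_width=bin_width, data=data)


def prefilter_cgis(
    cgis: Sequence[GenomicInterval],
    binned: BinnedDiffTrack,
    *,
    min_bins: int = 4,
    min_increase: float = 0.25,
    strong_increase: float = 0.50,
) -> list[GenomicInterval]:
    """Keep islands overlapping >= ``min_bins`` bins with a >= 25 %
    methylation increase, at least one of them >= 50 %."""
    out = []
    for iv in cgis:
        diffs = binned.diffs_overlapping(iv)
        diffs = diffs[~np.isnan(diffs)]
        if (diffs >= min_increase).sum() >= min_bins and (diffs >= strong_increase).any():
            out.append(iv)
    return out


def segment_profile(
    cgi: GenomicInterval,
    positions: np.ndarray,
    ratios: np.ndarray,
    *,
    n_segments: int = 40,
) -> np.ndarray:
    """Mean CpG methylation per equal-length segment of one island.

    The island ``[start, end)`` is split into ``n_segments`` segments
    of length L/n in real-valued coordinates; the CpG at position p
    belongs to segment ``floor((p - start) * n / L)`` (evaluated in
    exact integer arithmetic, so boundary assignment never depends on
    floating-point rounding).  Segments without CpGs are NaN.  CpGs
    outside the island are ignored.
    """
    length = cgi.end - cgi.start
    if length < 1:
        raise ValueError("CGI length must be >= 1 bp")
    positions = np.asarray(positions, dtype=np.int64)
    ratios = np.asarray(ratios, dtype=float)
    inside = (positions >= cgi.start) & (positions < cgi.end)
    pos_in, val_in = positions[inside], ratios[inside]
    seg = (pos_in - cgi.start) * n_segments // length
    sums = np.bincount(seg, weights=val_in, minlength=n_segments)
    counts = np.bincount(seg, minlength=n_segments).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def segment_profiles(
    cgis: Sequence[GenomicInterval],
    sites: pd.DataFrame,
    column: str,
    *,
    n_segments: int = 40,
) -> pd.DataFrame:
    """Segment profiles for many islands from a qualifying-site table.

    ``sites`` is the output of :func:`qualifying_cpg_ratios`;
    ``column`` selects the condition ("wt" or "ko").  Rows are indexed
    by island name.
    """
    by_chrom = {c: sub for c, sub in sites.groupby("chrom", sort=False)}
    rows = {}
    for iv in cgis:
        sub = by_chrom.get(iv.chrom)
        if sub is None:
            rows[iv.name] = np.full(n_segments, np.nan)
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        rows[iv.name] = segment_profile(
            iv, pos[lo:hi], sub[column].to_numpy()[lo:hi], n_segments=n_segments
        )
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"seg{i + 1}" for i in range(n_segments)])


def build_diff_matrix(
    wt_profiles: pd.DataFrame,
    ko_profiles: pd.DataFrame,
    *,
    max_nan: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-segment KO - WT differential methylation matrix.

    A cell is NaN when either condition's segment is NaN.  Rows (one
    per island) with more than ``max_nan`` NaN cells are excluded.
    Returns ``(matrix, excluded)`` where ``excluded`` records the
    dropped islands and their NaN counts.
    """
    if not wt_profiles.index.equals(ko_profiles.index):
        if set(wt_profiles.index) != set(ko_profiles.index):
            raise ValueError("WT and KO profiles cover different CGI sets")
        ko_profiles = ko_profiles.loc[wt_profiles.index]
    diff = ko_profiles - wt_profiles
    nan_counts = diff.isna().sum(axis=1)
    keep = nan_counts <= max_nan
    excluded = pd.DataFrame(
        {"name": diff.index[~keep], "n_nan": nan_counts[~keep].to_numpy(),
         "reason": f"more than {max_nan} NaN segments"}
    )
    if len(excluded):
        logger.info("excluded %d CGIs with > %d NaN segments", len(excluded), max_nan)
    return diff[keep], excluded


def _ranking_spans(n_segments: int) -> dict[str, slice]:
    # first quarter / central half / last quarter; 10/20/10 for 40 segments
    q = n_segments // 4
    return {"5prime": slice(0, q), "central": slice(q, n_segments - q),
            "3prime": slice(n_segments - q, n_segments)}


def _classify_shape(e5: float, ec: float, e3: float) -> str:
    """Deterministic class from the three span scores of one island.

    Bidirectional when the centre dominates both ends (central or
    whole-island hypermethylation) or when the weaker end carries at
    least half the gain of the stronger end; otherwise the class of
    the stronger end.  NaN scores count as no gain.
    """
    e5 = 0.0 if np.isnan(e5) else e5
    ec = 0.0 if np.isnan(ec) else ec
    e3 = 0.0 if np.isnan(e3) else e3
    hi, lo = max(e5, e3), min(e5, e3)
    if ec >= hi:
        return "bidirectional"
    if hi > 0 and lo >= 0.5 * hi:
        return "bidirectional"
    return "5prime" if e5 >= e3 else "3prime"


def rank_and_select(
    matrix: pd.DataFrame, *, top_n: int = 250, class_rule: str = "shape"
) -> pd.DataFrame:
    """Score, rank and select islands from the differential matrix.

    Each island gets three NaN-ignoring mean scores — 5' (segments
    1-10), central (11-30) and 3' (31-40) — and a 1-based descending
    rank per score (NaN score: ineligible for that ranking; ties broken
    by island name).  The union of the top ``top_n`` of each ranking is
    returned.

    Selected islands carry an assigned class.  The default
    ``class_rule="shape"`` classifies from the scores themselves (see
    :func:`_classify_shape`): it separates an island hypermethylated
    at both ends from one invaded at a single end, which a pure
    rank-comparison cannot, because a bidirectional island's end
    scores rival those of genuinely monodirectional islands.
    ``class_rule="best_rank"`` instead assigns the class of the
    ranking with the island's best (lowest) rank, ties resolving
    5' > bidirectional > 3'.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if matrix.empty:
        raise ValueError("differential matrix is empty")
    if class_rule not in {"shape", "best_rank"}:
        raise ValueError(f"unknown class_rule {class_rule!r}")
    spans = _ranking_spans(matrix.shape[1])
    values = matrix.to_numpy(dtype=float)
    out = pd.DataFrame(index=matrix.index)
    selected_any = np.zeros(len(matrix), dtype=bool)
    import warnings

    for ranking, span in spans.items():
        with warnings.catch_warnings():
            # an all-NaN span legitimately yields a NaN score
            warnings.simplefilter("ignore", category=RuntimeWarning)
            score = np.nanmean(values[:, span], axis=1)
        out[f"score_{ranking}"] = score
        eligible = ~np.isnan(score)
        order = sorted(
            np.flatnonzero(eligible),
            key=lambda i: (-score[i], str(matrix.index[i])),
        )
        rank = np.full(len(matrix), np.nan)
        for r, i in enumerate(order, start=1):
            rank[i] = r
        out[f"rank_{ranking}"] = rank
        in_top = np.zeros(len(matrix), dtype=bool)
        in_top[order[:top_n]] = True
        out[f"selected_{ranking}"] = in_top
        selected_any |= in_top

    if class_rule == "best_rank":
        ranks = out[[f"rank_{r}" for r in RANKINGS]].to_numpy()
        best = np.argmin(np.where(np.isnan(ranks), np.inf, ranks), axis=1)
        out["class"] = [CLASS_OF_RANKING[RANKINGS[i]] for i in best]
    else:
        out["class"] = [
            _classify_shape(e5, ec, e3)
            for e5, ec, e3 in zip(out["score_5prime"], out["score_central"],
                                  out["score_3prime"])
        ]
    calls = out[selected_any].copy()
    calls.index.name = "name"
    return calls


def aggregate_class_profiles(calls: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-class NaN-ignoring mean differential profile across segments."""
    rows = {}
    for cls in ("5prime", "bidirectional", "3prime"):
        members = calls.index[calls["class"] == cls]
        if len(members) == 0:
            logger.warning("class %s has no members; omitted from profiles", cls)
            continue
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            rows[cls] = np.nanmean(matrix.loc[members].to_numpy(dtype=float), axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns)


def detect_encroachment(
    wt_tracks,
    ko_tracks,
    cgis: Sequence[GenomicInterval],
    genome: GenomeLayout,
    *,
    bin_width: int = 40,
    min_cov: int = 4,
    min_bins: int = 4,
    min_increase: float = 0.25,
    strong_increase: float = 0.50,
    n_segments: int = 40,
    max_nan: int = 30,
    top_n: int = 250,
    combine: str = "mean_ratio",
    class_rule: str = "shape",
) -> dict:
    """Run the full detector; returns every intermediate product.

    Keys of the result: ``sites`` (qualifying CpG levels), ``binned``,
    ``candidates``, ``wt_profiles``, ``ko_profiles``, ``matrix``,
    ``excluded``, ``calls``, ``class_profiles``.
    """
    sites = qualifying_cpg_ratios(wt_tracks, ko_tracks, min_cov=min_cov, combine=combine)
    binned = bin_methylation(
        wt_tracks, ko_tracks, genome, bin_width=bin_width, min_cov=min_cov, combine=combine
    )
    candidates = prefilter_cgis(
        cgis, binned, min_bins=min_bins, min_increase=min_increase,
        strong_increase=strong_increase,
    )
    result = {"sites": sites, "binned": binned, "candidates": candidates}
    if not candidates:
        logger.warning("no CGI passed the prefilter")
        empty_cols = [f"seg{i + 1}" for i in range(n_segments)]
        result.update(
            wt_profiles=pd.DataFrame(columns=empty_cols),
            ko_profiles=pd.DataFrame(columns=empty_cols),
            matrix=pd.DataFrame(columns=empty_cols),
            excluded=pd.DataFrame(columns=["name", "n_nan", "reason"]),
            calls=pd.DataFrame(),
            class_profiles=pd.DataFrame(columns=empty_cols),
        )
        return result
    wt_prof = segment_profiles(candidates, sites, "wt", n_segments=n_segments)
    ko_prof = segment_profiles(candidates, sites, "ko", n_segments=n_segments)
    matrix, excluded = build_diff_matrix(wt_prof, ko_prof, max_nan=max_nan)
    result.update(wt_profiles=wt_prof, ko_profiles=ko_prof, matrix=matrix,
                  excluded=excluded)
    if matrix.empty:
        logger.warning("all candidate CGIs excluded by the NaN rule")
        result.update(calls=pd.DataFrame(), class_profiles=pd.DataFrame())
        return result
    calls = rank_and_select(matrix, top_n=top_n, class_rule=class_rule)
    result["calls"] = calls
    result["class_profiles"] = aggregate_class_profiles(calls, matrix)
    return result
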