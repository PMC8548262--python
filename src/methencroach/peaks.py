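"""Reproducible peaks, RPKM occupancy and fold-change differential binding.

Reproducibility across ChIP-seq replicates is assessed with two peak
tiers per replicate: high-confidence calls (q <= 0.05) and relaxed
"FDR50" calls (q <= 0.5).  The union of all replicates' FDR50 peaks is
merged into maximal connected intervals, and a merged interval is
reproducible when every replicate contributes at least one overlapping
peak to it.  Experiments with a single replicate fall back to their
high-confidence peaks unchanged.

Occupancy is quantified as RPKM = count * 1e9 / (peak length * library
size), fragments counted with a >= 1 bp overlap rule, and differential
binding is called on the ratio of condition-mean RPKM (with a small
pseudocount); regions with a fold-change above 2 in either direction
are differential, and per-antibody calls for the same protein are
combined by interval union of the up- and down-regulated sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .io_formats import GenomicInterval, NarrowPeakRecord

PEAK_COLS = ["Chromosome", "Start", "End", "Name"]


def _to_frame(peaks) -> pd.DataFrame:
    """Normalise a peak collection to a Chromosome/Start/End/Name frame."""
    if isinstance(peaks, pd.DataFrame):
        df = peaks.copy()
        if "Chromosome" not in df.columns:
            df = df.rename(columns={"chrom": "Chromosome", "start": "Start",
                                    "end": "End", "name": "Name"})
        if "Name" not in df.columns:
            df["Name"] = [f"iv_{i + 1}" for i in range(len(df))]
        return df[PEAK_COLS].reset_index(drop=True)
    rows = []
    for i, p in enumerate(peaks):
        if isinstance(p, (NarrowPeakRecord, GenomicInterval)):
            rows.append((p.chrom, p.start, p.end, p.name or f"iv_{i + 1}"))
        else:  # (chrom, start, end[, name]) tuple
            rows.append((p[0], p[1], p[2], p[3] if len(p) > 3 else f"iv_{i + 1}"))
    return pd.DataFrame(rows, columns=PEAK_COLS)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/bookended intervals into maximal ones."""
    if df.empty:
        return pd.DataFrame(columns=["Chromosome", "Start", "End"])
    merged = pr.PyRanges(df[["Chromosome", "Start", "End"]]).merge().df
    return merged.sort_values(["Chromosome", "Start"]).reset_index(drop=True)


def reproducible_peaks(
    fdr50_by_replicate: Sequence, *, merged_extent: bool = True
) -> pd.DataFrame:
    """Identify peaks reproducible across all replicates.

    ``fdr50_by_replicate`` holds one relaxed-threshold peak collection
    per replicate.  With a single replicate the caller passes the
    high-confidence set instead, which is returned unchanged.  The
    result is a frame of merged intervals with a ``Support`` column
    listing the contributing peak names per replicate.
    """
    if not len(fdr50_by_replicate):
        raise ValueError("need at least one replicate peak set")
    frames = [_to_frame(p) for p in fdr50_by_replicate]
    if len(frames) == 1:
        out = frames[0].copy()
        out["Support"] = out["Name"]
        return out[["Chromosome", "Start", "End", "Name", "Support"]]
    merged = merge_intervals(pd.concat(frames, ignore_index=True))
    if merged.empty or any(f.empty for f in frames):
        return pd.DataFrame(columns=["Chromosome", "Start", "End", "Name", "Support"])
    merged_pr = pr.PyRanges(merged)
    merged_keys = {(c, s, e): i for i, (c, s, e) in
                   enumerate(zip(merged["Chromosome"], merged["Start"], merged["End"]))}
    # bases covered by every replicate: successive base-level intersection
    common = pr.PyRanges(merge_intervals(frames[0]))
    for frame in frames[1:]:
        common = common.intersect(pr.PyRanges(merge_intervals(frame)))
        if common.empty:
            return pd.DataFrame(columns=["Chromosome", "Start", "End", "Name", "Support"])
    # a merged union interval is reproducible iff it contains such a base
    keep = np.zeros(len(merged), dtype=bool)
    hit = merged_pr.overlap(common).df
    for c, s, e in zip(hit.get("Chromosome", []), hit.get("Start", []), hit.get("End", [])):
        keep[merged_keys[(c, s, e)]] = True
    support = [[] for _ in range(len(merged))]
    for rep_i, frame in enumerate(frames):
        joined = merged_pr.join(pr.PyRanges(frame)).df
        for _, row in joined.iterrows():
            i = merged_keys[(row["Chromosome"], row["Start"], row["End"])]
            support[i].append(f"rep{rep_i + 1}:{row['Name']}")
    out = merged[keep].reset_index(drop=True)
    out["Name"] = [f"reproducible_{i + 1}" for i in range(len(out))]
    out["Support"] = [";".join(s) for i, s in enumerate(support) if keep[i]]
    return out


@dataclass
class OccupancyTable:
    """Per-peak raw fragment counts, library sizes and RPKM."""

    peaks: pd.DataFrame  # Chromosome/Start/End/Name
    counts: pd.DataFrame  # peaks x samples, raw fragment counts
    library_sizes: pd.Series  # per sample, total fragments

    @property
    def rpkm(self) -> pd.DataFrame:
        lengths = (self.peaks["End"] - self.peaks["Start"]).to_numpy(dtype=float)
        return self.counts * 1e9 / (lengths[:, None] * self.library_sizes.to_numpy()[None, :])


def count_fragments(peaks, fragments_by_sample: Mapping[str, pd.DataFrame]) -> OccupancyTable:
    """Count fragments overlapping each peak by >= 1 bp, per sample.

    ``fragments_by_sample`` maps sample name to a frame with
    chrom/start/end columns; the library size is the total number of
    fragments in the file.
    """
    peaks_df = _to_frame(peaks)
    counts = {}
    lib_sizes = {}
    for sample, frags in fragments_by_sample.items():
        f = frags.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})
        n_total = len(f)
        if n_total == 0:
            raise ValueError(f"sample {sample!r} has zero library size")
        lib_sizes[sample] = n_total
        per_peak = np.zeros(len(peaks_df), dtype=np.int64)
        for chrom, sub in f.groupby("Chromosome", sort=False):
            starts = np.sort(sub["Start"].to_numpy())
            ends = np.sort(sub["End"].to_numpy())
            mask = peaks_df["Chromosome"] == chrom
            ps = peaks_df.loc[mask, "Start"].to_numpy()
            pe = peaks_df.loc[mask, "End"].to_numpy()
            # fragment overlaps iff frag_start < peak_end and frag_end > peak_start
            n = len(starts)
            not_overlapping = (n - np.searchsorted(starts, pe, side="left")) + \
                np.searchsorted(ends, ps, side="right")
            per_peak[mask.to_numpy()] = n - not_overlapping
        counts[sample] = per_peak
    counts_df = pd.DataFrame(counts, index=peaks_df["Name"])
    return OccupancyTable(peaks_df, counts_df, pd.Series(lib_sizes))


def differential_binding(
    occupancy_ko: OccupancyTable,
    occupancy_wt: OccupancyTable,
    *,
    fc_threshold: float = 2.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Fold-change differential binding between matched occupancy tables.

    FC = (mean KO RPKM + pseudocount) / (mean WT RPKM + pseudocount);
    a peak is ``up`` when FC exceeds the threshold and ``down`` when
    1/FC does (fold-change *higher than* the threshold, strict).
    """
    if not occupancy_ko.peaks[PEAK_COLS].equals(occupancy_wt.peaks[PEAK_COLS]):
        raise ValueError("KO and WT occupancy tables cover different peak sets")
    mean_ko = occupancy_ko.rpkm.mean(axis=1)
    mean_wt = occupancy_wt.rpkm.mean(axis=1)
    fc = (mean_ko + pseudocount) / (mean_wt + pseudocount)
    direction = np.where(fc > fc_threshold, "up",
                         np.where(fc < 1.0 / fc_threshold, "down", "unchanged"))
    out = occupancy_ko.peaks.copy()
    out["mean_rpkm_ko"] = mean_ko.to_numpy()
    out["mean_rpkm_wt"] = mean_wt.to_numpy()
    out["fold_change"] = fc.to_numpy()
    out["direction"] = direction
    return out


def union_across_antibodies(callsets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union of per-antibody differential calls for one protein.

    Up- and down-regulated intervals are merged separately across
    antibodies; the result carries a ``direction`` column.
    """
    if not len(callsets):
        raise ValueError("need at least one callset")
    pieces = []
    for direction in ("up", "down"):
        sub = pd.concat(
            [cs[cs["direction"] == direction] for cs in callsets], ignore_index=True
        )
        if sub.empty:
            continue
        merged = merge_intervals(sub)
        merged["direction"] = direction
        pieces.append(merged)
    if not pieces:
        return pd.DataFrame(columns=["Chromosome", "Start", "End", "direction"])
    return pd.concat(pieces, ignore_index=True)


def intersect_signatures(set_a, set_b) -> pd.DataFrame:
    """Base-pair intersection of two interval sets (merged, with parents).

    Returns the maximal intervals covered by both sets; each row lists
    the names of the contributing intervals from A and B.
    """
    a, b = _to_frame(set_a), _to_frame(set_b)
    if a.empty or b.empty:
        return pd.DataFrame(columns=["Chromosome", "Start", "End", "ParentsA", "ParentsB"])
    joined = pr.PyRanges(a).join(pr.PyRanges(b)).df
    if joined.empty:
        return pd.DataFrame(columns=["Chromosome", "Start", "End", "ParentsA", "ParentsB"])
    joined["IStart"] = joined[["Start", "Start_b"]].max(axis=1)
    joined["IEnd"] = joined[["End", "End_b"]].min(axis=1)
    pieces = joined[["Chromosome", "IStart", "IEnd", "Name", "Name_b"]].rename(
        columns={"IStart": "Start", "IEnd": "End"}
    )
    merged = merge_intervals(pieces)
    parents_a, parents_b = [], []
    for _, row in merged.iterrows():
        hit = pieces[(pieces["Chromosome"] == row["Chromosome"])
                     & (pieces["Start"] < row["End"]) & (pieces["End"] > row["Start"])]
        parents_a.append(";".join(sorted(set(hit["Name"]))))
        parents_b.append(";".join(sorted(set(hit["Name_b"]))))
    merged["ParentsA"] = parents_a
    merged["ParentsB"] = parents_b
    return merged
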