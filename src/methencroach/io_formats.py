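"""Readers and writers for the external file dialects the pipeline touches.

All coordinates are normalised to a single internal convention: 0-based,
half-open ``[start, end)`` intervals, matching BED.  BSMAP ``methratio``
tables carry 1-based positions and are shifted on input (switchable with
``one_based=False`` for files already in the internal convention).

Formats handled here: BED3/6, ENCODE narrowPeak, UCSC ``cpgIslandExt``,
methratio-style CpG tables, two-column ``chrom.sizes`` files, and plain
TSV outputs whose header line starts with ``#``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of chromosomes with their lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in GenomeLayout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome layout") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __iter__(self):
        return iter(self.chromosomes)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NarrowPeakRecord:
    """One ENCODE narrowPeak line (10 columns)."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    signal_value: float
    p_value: float  # -log10
    q_value: float  # -log10
    summit: int  # offset from start; -1 when not determined

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid peak {self.chrom}:{self.start}-{self.end}")
        if not (-1 <= self.summit < self.end - self.start):
            raise ValueError(
                f"summit offset {self.summit} outside [-1, {self.end - self.start}) "
                f"for peak {self.name}"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.name, self.strand)


class MethylationTrack:
    """Per-sample CpG methylation map.

    Backed by a DataFrame with columns ``chrom``, ``pos`` (0-based),
    ``strand``, ``meth`` (methylated read count), ``cov`` (total reads)
    and ``ratio``.  ``ratio`` is always recomputed as ``meth / cov`` so
    the invariant ``meth <= cov``, ``cov >= 1`` stays testable.
    """

    COLUMNS = ["chrom", "pos", "strand", "meth", "cov", "ratio"]

    def __init__(self, df: pd.DataFrame, name: str = "sample"):
        missing = [c for c in ("chrom", "pos", "strand", "meth", "cov") if c not in df.columns]
        if missing:
            raise ValueError(f"MethylationTrack missing columns: {missing}")
        df = df.copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["cov"] = df["cov"].astype(np.int64)
        if (df["cov"] < 1).any():
            raise ValueError("coverage must be >= 1 for every retained CpG record")
        if (df["meth"] > df["cov"]).any() or (df["meth"] < 0).any():
            raise ValueError("methylated count must satisfy 0 <= meth <= cov")
        df["ratio"] = df["meth"] / df["cov"]
        self.df = (
            df[self.COLUMNS]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.name = name

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MethylationTrack({self.name!r}, {len(self)} CpGs)"

    @classmethod
    def from_arrays(cls, chrom, pos, strand, meth, cov, name="sample") -> "MethylationTrack":
        return cls(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "strand": strand, "meth": meth, "cov": cov}
            ),
            name=name,
        )


# ---------------------------------------------------------------------------
# methratio-style CpG tables
# ---------------------------------------------------------------------------

METHRATIO_HEADER = ["chrom", "pos", "strand", "context", "ratio", "meth", "cov"]


def read_methratio(
    path: str | Path,
    *,
    one_based: bool = True,
    merge_strands: bool = False,
    name: str | None = None,
) -> MethylationTrack:
    """Read a BSMAP-methratio-style CpG table.

    Expects a tab-separated table with columns chrom, position, strand,
    context, ratio, methylated count, total count.  Only CG-context rows
    are retained (others are dropped and counted in a log message); the
    methylation ratio is recomputed from the counts, never trusted from
    the file.  Rows with zero coverage are rejected and logged.

    Parameters
    ----------
    one_based
        Treat input positions as 1-based (the methratio convention) and
        shift to the internal 0-based convention.
    merge_strands
        Merge the two strands of each symmetric CpG (a ``-`` record at
        position p+1 pairs with a ``+`` record at p) by summing counts.
        Off by default: reads are kept per strand as reported.
    """
    path = Path(path)
    rows: list[tuple] = []
    n_non_cg = 0
    n_zero_cov = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"chr", "chrom", "chromosome"}:
                continue  # header line
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected >=7 columns, got {len(fields)}")
            chrom, pos_s, strand, context = fields[0], fields[1], fields[2], fields[3]
            try:
                pos = int(pos_s)
                meth = int(fields[5])
                cov = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})") from None
            if context != "CG":
                n_non_cg += 1
                continue
            if cov < 1:
                n_zero_cov += 1
                continue
            if meth < 0 or meth > cov:
                raise ValueError(f"{path}:{lineno}: methylated count {meth} outside [0, {cov}]")
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, pos - 1 if one_based else pos, strand, meth, cov))
    if n_non_cg:
        logger.info("%s: dropped %d non-CG context rows", path.name, n_non_cg)
    if n_zero_cov:
        logger.info("%s: rejected %d zero-coverage rows", path.name, n_zero_cov)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "cov"])
    if merge_strands and len(df):
        # a minus-strand CpG at p pairs with the plus-strand CpG at p-1
        df["pair_pos"] = np.where(df["strand"] == "-", df["pos"] - 1, df["pos"])
        grouped = (
            df.groupby(["chrom", "pair_pos"], as_index=False)
            .agg(meth=("meth", "sum"), cov=("cov", "sum"))
            .rename(columns={"pair_pos": "pos"})
        )
        grouped["strand"] = "+"
        df = grouped
    return MethylationTrack(df, name=name or path.stem)


def write_methratio(track: MethylationTrack, path: str | Path, *, one_based: bool = True) -> None:
    """Write a track in the methratio dialect (round-trips with the reader)."""
    df = track.df.copy()
    df["pos"] = df["pos"] + (1 if one_based else 0)
    df["context"] = "CG"
    out = df[["chrom", "pos", "strand", "context", "ratio", "meth", "cov"]]
    with open(path, "w") as fh:
        fh.write("chr\tpos\tstrand\tcontext\tratio\tC_count\tCT_count\n")
        out.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# BED / narrowPeak / cpgIslandExt
# ---------------------------------------------------------------------------


def _check_against_genome(chrom: str, start: int, end: int, genome: GenomeLayout | None,
                          where: str) -> None:
    if genome is None:
        return
    if chrom not in genome:
        raise ValueError(f"{where}: chromosome {chrom!r} absent from genome layout")
    if end > genome.length_of(chrom):
        raise ValueError(
            f"{where}: interval end {end} beyond {chrom} length {genome.length_of(chrom)}"
        )


def read_bed(path: str | Path, genome: GenomeLayout | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6 into internal intervals."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"region_{lineno}"
            strand = f[5] if len(f) > 5 else "."
            _check_against_genome(chrom, start, end, genome, f"{path}:{lineno}")
            out.append(GenomicInterval(chrom, start, end, name, strand))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    genome: GenomeLayout | None = None,
) -> None:
    """Write intervals as BED6 (0-based half-open, as stored)."""
    intervals = list(intervals)
    for iv in intervals:
        _check_against_genome(iv.chrom, iv.start, iv.end, genome, f"write_bed({iv.name})")
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def read_narrowpeak(
    path: str | Path, genome: GenomeLayout | None = None
) -> list[NarrowPeakRecord]:
    """Read a 10-column ENCODE narrowPeak file."""
    path = Path(path)
    out: list[NarrowPeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 10:
                raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(f)}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            _check_against_genome(chrom, start, end, genome, f"{path}:{lineno}")
            try:
                rec = NarrowPeakRecord(
                    chrom, start, end, f[3], int(f[4]), f[5],
                    float(f[6]), float(f[7]), float(f[8]), int(f[9]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            out.append(rec)
    return out


def write_narrowpeak(records: Iterable[NarrowPeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}"
                f"\t{r.signal_value:g}\t{r.p_value:g}\t{r.q_value:g}\t{r.summit}\n"
            )


def read_cgi_table(
    path: str | Path, genome: GenomeLayout | None = None
) -> list[GenomicInterval]:
    """Read CpG islands from a UCSC ``cpgIslandExt`` table or a plain BED.

    The cpgIslandExt dialect carries a leading integer ``bin`` column
    before chrom/start/end/name; it is detected per row and skipped.
    BED3 rows receive autogenerated names.  Duplicate names are kept
    with a warning.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            # cpgIslandExt: bin, chrom, chromStart, chromEnd, name, ...
            offset = 0
            try:
                int(f[0])
                offset = 1  # leading bin column
            except ValueError:
                pass
            if len(f) < offset + 3:
                raise ValueError(f"{path}:{lineno}: too few columns for a CGI row")
            chrom = f[offset]
            start, end = int(f[offset + 1]), int(f[offset + 2])
            name = f[offset + 3] if len(f) > offset + 3 else f"CGI_{len(out) + 1}"
            # UCSC CGI names ("CpG: 116") are not unique; disambiguate
            if name in seen:
                logger.warning("%s:%d: duplicate CGI name %r kept", path.name, lineno, name)
            seen.add(name)
            _check_against_genome(chrom, start, end, genome, f"{path}:{lineno}")
            out.append(GenomicInterval(chrom, start, end, name))
    return out


# ---------------------------------------------------------------------------
# chrom.sizes and generic tables
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ValueError(f"{path}:{lineno}: chrom.sizes needs 2 columns")
            chroms.append((f[0], int(f[1])))
    return GenomeLayout(tuple(chroms))


def write_chrom_sizes(genome: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome:
            fh.write(f"{name}\t{length}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV whose single header line starts with '#'."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, na_rep="NaN")


def read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header line")
        columns = header[1:].split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=columns, na_values=["NaN"])
    return df


# ---------------------------------------------------------------------------
# interval <-> DataFrame helpers shared by the interval-algebra modules
# ---------------------------------------------------------------------------


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Intervals as a pyranges-style frame (Chromosome/Start/End/Name/Strand)."""
    return pd.DataFrame(
        {
            "Chromosome": [iv.chrom for iv in intervals],
            "Start": [iv.start for iv in intervals],
            "End": [iv.end for iv in intervals],
            "Name": [iv.name or "." for iv in intervals],
            "Strand": [iv.strand for iv in intervals],
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    names = df["Name"] if "Name" in df else [None] * len(df)
    strands = df["Strand"] if "Strand" in df else ["."] * len(df)
    return [
        GenomicInterval(c, int(s), int(e), n if n not in (None, ".") else None, st)
        for c, s, e, n, st in zip(df["Chromosome"], df["Start"], df["End"], names, strands)
    ]
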