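"""Priority-ordered genomic-context annotation.

Each query region receives exactly one context label, chosen by testing
for >= 1 bp overlap against feature classes in a fixed priority order:

    Promoter.Up > Promoter.Down > Exons > Introns > TES
    > 5' Distal > 3' Distal > Intergenic

"Upstream"/"downstream" are 5'/3' of the TSS on the gene's own strand.
Distal features extend to 50 kbp but exclude the promoter portion; the
TES feature is a +/- 2 kbp window around the transcription end site
(the width is configurable).  Features are pooled across all isoforms.
A 1-kbp tiling of the genome annotated the same way gives the
background label distribution against which region sets are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeLayout, GenomicInterval

PRIORITY_ORDER = [
    "Promoter.Up",
    "Promoter.Down",
    "Exons",
    "Introns",
    "TES",
    "5p_Distal",
    "3p_Distal",
]
INTERGENIC = "Intergenic"
ALL_LABELS = PRIORITY_ORDER + [INTERGENIC]


@dataclass(frozen=True)
class GeneModel:
    """Single transcript model: TSS/TES with exon blocks.

    ``tss``/``tes`` are 0-based positions; for a minus-strand gene the
    TSS is numerically greater than the TES.  Exons are half-open
    intervals in genomic order; introns are the gaps between them.
    """

    name: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.name}: strand must be + or -")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.name}: TSS equals TES")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"gene {self.name}: + strand gene with TSS > TES")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"gene {self.name}: - strand gene with TSS < TES")
        exons = sorted(self.exons)
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if a2 < b1:
                raise ValueError(f"gene {self.name}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        exons = sorted(self.exons)
        return tuple((b1, a2) for (_, b1), (a2, _) in zip(exons, exons[1:]) if b1 < a2)


def read_genes_tsv(path) -> list[GeneModel]:
    """Read the simplified gene table: gene, chrom, strand, tss, tes, exons.

    ``exons`` is a comma-separated list of ``start-end`` blocks (may be
    empty).  Header line starts with '#'.
    """
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: gene table needs >=5 columns")
            exons = ()
            if len(f) > 5 and f[5]:
                exons = tuple(
                    tuple(int(x) for x in block.split("-")) for block in f[5].split(",")
                )
            genes.append(GeneModel(f[0], f[1], f[2], int(f[3]), int(f[4]), exons))
    return genes


def write_genes_tsv(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tchrom\tstrand\ttss\ttes\texons\n")
        for g in genes:
            blocks = ",".join(f"{a}-{b}" for a, b in g.exons)
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\t{blocks}\n")


def _clip(start: int, end: int, length: int) -> tuple[int, int] | None:
    s, e = max(0, start), min(length, end)
    return (s, e) if s < e else None


def build_context_features(
    genes: Sequence[GeneModel],
    genome: GenomeLayout,
    *,
    promoter_flank: int = 2_000,
    distal_extent: int = 50_000,
    tes_flank: int = 2_000,
) -> dict[str, pd.DataFrame]:
    """Build the labelled feature intervals for every priority class.

    Returns a mapping label -> DataFrame (Chromosome/Start/End/Gene).
    Intervals are clipped to chromosome bounds.  Distal features
    exclude their promoter portion by construction (they start where
    the promoter ends); overlaps *between* classes are resolved later
    by priority, not here.
    """
    rows: dict[str, list[tuple[str, int, int, str]]] = {lab: [] for lab in PRIORITY_ORDER}
    for g in genes:
        length = genome.length_of(g.chrom)
        sgn = 1 if g.strand == "+" else -1
        # promoter halves, strand-aware
        if sgn == 1:
            prom_up = _clip(g.tss - promoter_flank, g.tss, length)
            prom_down = _clip(g.tss, g.tss + promoter_flank, length)
            distal5 = _clip(g.tss - distal_extent, g.tss - promoter_flank, length)
            distal3 = _clip(g.tes + promoter_flank, g.tes + distal_extent, length)
        else:
            prom_up = _clip(g.tss, g.tss + promoter_flank, length)
            prom_down = _clip(g.tss - promoter_flank, g.tss, length)
            distal5 = _clip(g.tss + promoter_flank, g.tss + distal_extent, length)
            distal3 = _clip(g.tes - distal_extent, g.tes - promoter_flank, length)
        tes_win = _clip(g.tes - tes_flank, g.tes + tes_flank, length)
        for label, iv in (
            ("Promoter.Up", prom_up),
            ("Promoter.Down", prom_down),
            ("TES", tes_win),
            ("5p_Distal", distal5),
            ("3p_Distal", distal3),
        ):
            if iv is not None:
                rows[label].append((g.chrom, iv[0], iv[1], g.name))
        for a, b in g.exons:
            iv = _clip(a, b, length)
            if iv is not None:
                rows["Exons"].append((g.chrom, iv[0], iv[1], g.name))
        for a, b in g.introns:
            iv = _clip(a, b, length)
            if iv is not None:
                rows["Introns"].append((g.chrom, iv[0], iv[1], g.name))
    return {
        lab: pd.DataFrame(v, columns=["Chromosome", "Start", "End", "Gene"])
        for lab, v in rows.items()
    }


def _overlaps_any(chrom: str, start: int, end: int, feat: pd.DataFrame) -> bool:
    if feat.empty:
        return False
    sub = feat[feat["Chromosome"] == chrom]
    if sub.empty:
        return False
    return bool(((sub["Start"].values < end) & (sub["End"].values > start)).any())


def annotate_regions(
    regions: Sequence[GenomicInterval],
    features: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Assign each region its highest-priority overlapping context label.

    A region overlapping no feature is ``Intergenic``.  The result is a
    partition: exactly one label per region.
    """
    labels = []
    for iv in regions:
        label = INTERGENIC
        for lab in PRIORITY_ORDER:
            if _overlaps_any(iv.chrom, iv.start, iv.end, features.get(lab, pd.DataFrame())):
                label = lab
                break
        labels.append(label)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in regions],
            "start": [iv.start for iv in regions],
            "end": [iv.end for iv in regions],
            "name": [iv.name or "." for iv in regions],
            "label": labels,
        }
    )


def background_distribution(
    genome: GenomeLayout,
    features: Mapping[str, pd.DataFrame],
    *,
    bin_size: int = 1_000,
) -> pd.DataFrame:
    """Label frequency over a ``bin_size`` tiling of the whole genome.

    Every bin (including a trailing partial bin) is annotated with the
    same priority rule; returned frequencies sum to 1.
    """
    bins: list[GenomicInterval] = []
    for chrom, length in genome:
        for s in range(0, length, bin_size):
            bins.append(GenomicInterval(chrom, s, min(s + bin_size, length)))
    annotated = annotate_regions(bins, features)
    counts = annotated["label"].value_counts()
    out = pd.DataFrame(
        {
            "label": ALL_LABELS,
            "count": [int(counts.get(lab, 0)) for lab in ALL_LABELS],
        }
    )
    out["frequency"] = out["count"] / out["count"].sum()
    return out


def assign_genes(
    regions: Sequence[GenomicInterval],
    features: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Associate each region with all genes whose promoter it overlaps.

    The promoter is the union of the Promoter.Up and Promoter.Down
    halves; a region may hit several genes' promoters (all are
    reported) or none (empty list).
    """
    promoters = pd.concat(
        [features.get("Promoter.Up", pd.DataFrame()),
         features.get("Promoter.Down", pd.DataFrame())],
        ignore_index=True,
    )
    gene_lists = []
    for iv in regions:
        if promoters.empty:
            gene_lists.append([])
            continue
        sub = promoters[promoters["Chromosome"] == iv.chrom]
        hit = sub[(sub["Start"] < iv.end) & (sub["End"] > iv.start)]
        gene_lists.append(sorted(set(hit["Gene"])))
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in regions],
            "start": [iv.start for iv in regions],
            "end": [iv.end for iv in regions],
            "name": [iv.name or "." for iv in regions],
            "genes": [",".join(g) for g in gene_lists],
            "n_genes": [len(g) for g in gene_lists],
        }
    )
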