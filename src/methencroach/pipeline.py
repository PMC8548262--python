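"""End-to-end orchestration of the WGBS and ChIP analyses.

Two pipelines compose the stage modules:

* ``run_wgbs_pipeline`` — methylation tracks -> DMCs, DMRs over the
  standard region families, and CGI encroachment calls.
* ``run_chip_pipeline`` — replicate peak tiers + fragment BEDs ->
  reproducible peaks, RPKM occupancy, fold-change differential calls,
  per-protein union across antibodies, and genomic-context annotation.

Both validate their inputs before any computation, log per-stage record
counts, write every product as '#'-headed TSV or BED, and are
deterministic: re-running on identical inputs reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import encroachment as enc
from . import methylation as meth
from . import peaks as pk
from .io_formats import (
    GenomicInterval,
    read_bed,
    read_cgi_table,
    read_chrom_sizes,
    read_methratio,
    read_narrowpeak,
    write_bed,
    write_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of both pipelines.

    Threshold defaults are the standard analysis settings: coverage
    >= 10 in all samples for DMC/DMR calling and >= 4 per replicate
    for encroachment; 25-percentage-point minimum difference at FDR
    0.05; fold-change 2; 40-bp bins, 40 segments, <= 30 NaN segments,
    top 250 per ranking; promoters TSS +/- 2 kbp, distal up to 50 kbp,
    1-kbp background bins.
    """

    # inputs (paths); WGBS side
    wt_methratio: list[str] = field(default_factory=list)
    ko_methratio: list[str] = field(default_factory=list)
    cgi_table: str | None = None
    chrom_sizes: str | None = None
    genes: str | None = None
    ground_truth: str | None = None
    # ChIP side: [{name, wt: {high: [...], fdr50: [...], fragments: [...]}, ko: {...}}]
    antibodies: list[dict] = field(default_factory=list)

    # thresholds
    min_cov_dmc: int = 10
    min_cov_encroach: int = 4
    min_diff_pp: float = 25.0
    fdr: float = 0.05
    fc_threshold: float = 2.0
    pseudocount: float = 0.1
    bin_width: int = 40
    n_segments: int = 40
    max_nan: int = 30
    top_n: int = 250
    min_bins: int = 4
    min_increase: float = 0.25
    strong_increase: float = 0.50
    promoter_flank: int = 2_000
    shore_width: int = 2_000
    distal_extent: int = 50_000
    tes_flank: int = 2_000
    background_bin: int = 1_000
    dmr_families: list[str] = field(
        default_factory=lambda: ["CGI", "CGI_shore", "promoter",
                                 "window100", "window500", "window1000"]
    )
    merge_strands: bool = False
    combine: str = "mean_ratio"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.fdr <= 1.0):
            raise ValueError("fdr must be in (0, 1]")
        if not (0.0 <= self.min_diff_pp <= 100.0):
            raise ValueError("min_diff_pp must be in [0, 100]")
        if self.fc_threshold <= 0 or self.pseudocount < 0:
            raise ValueError("fc_threshold must be > 0 and pseudocount >= 0")
        for name in ("min_cov_dmc", "min_cov_encroach", "bin_width", "n_segments",
                     "top_n", "background_bin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"config is missing the {what} input")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} input not found: {p}")
    return p


def _matrix_table(matrix: pd.DataFrame) -> pd.DataFrame:
    out = matrix.copy()
    out.insert(0, "name", out.index)
    return out.reset_index(drop=True)


def run_wgbs_pipeline(config: PipelineConfig, outdir) -> dict:
    """DMC/DMR calling plus encroachment detection; writes all products."""
    config.validate()
    outdir = Path(outdir)
    genome_path = _require(config.chrom_sizes, "chrom.sizes")
    cgi_path = _require(config.cgi_table, "CGI table")
    if not config.wt_methratio or not config.ko_methratio:
        raise FileNotFoundError("need >=1 WT and >=1 KO methratio input")
    wt_paths = [_require(p, "WT methratio") for p in config.wt_methratio]
    ko_paths = [_require(p, "KO methratio") for p in config.ko_methratio]
    genes_path = _require(config.genes, "gene table") if config.genes else None
    outdir.mkdir(parents=True, exist_ok=True)

    genome = read_chrom_sizes(genome_path)
    cgis = read_cgi_table(cgi_path, genome)
    genes = ann.read_genes_tsv(genes_path) if genes_path else []
    wt = [read_methratio(p, merge_strands=config.merge_strands) for p in wt_paths]
    ko = [read_methratio(p, merge_strands=config.merge_strands) for p in ko_paths]
    stage_log = [("input_cgis", len(cgis), ""), ("input_genes", len(genes), "")]
    for t in wt + ko:
        stage_log.append((f"input_cpgs_{t.name}", len(t), ""))

    dmc = meth.call_dmc(wt, ko, min_diff=config.min_diff_pp, fdr=config.fdr,
                        min_cov=config.min_cov_dmc)
    write_table(dmc, outdir / "dmc.tsv")
    stage_log.append(("dmc_tested", len(dmc), f"significant={int(dmc['significant'].sum())}"))

    families = meth.make_region_families(
        genome, cgis, genes, shore_width=config.shore_width,
        promoter_flank=config.promoter_flank,
    )
    dmr_results = {}
    for fam in config.dmr_families:
        regions = families.get(fam, [])
        if not regions:
            logger.info("family %s has no regions; skipped", fam)
            continue
        dmr = meth.call_dmr(regions, wt, ko, min_diff=config.min_diff_pp,
                            fdr=config.fdr, min_cov=config.min_cov_dmc)
        write_table(dmr, outdir / f"dmr_{fam}.tsv")
        dmr_results[fam] = dmr
        stage_log.append(
            (f"dmr_{fam}", len(dmr), f"significant={int(dmr['significant'].sum())}")
        )

    det = enc.detect_encroachment(
        wt, ko, cgis, genome, bin_width=config.bin_width,
        min_cov=config.min_cov_encroach, min_bins=config.min_bins,
        min_increase=config.min_increase, strong_increase=config.strong_increase,
        n_segments=config.n_segments, max_nan=config.max_nan, top_n=config.top_n,
        combine=config.combine,
    )
    write_bed(det["candidates"], outdir / "candidates.bed", genome)
    write_table(_matrix_table(det["matrix"]), outdir / "diff_matrix.tsv")
    calls = det["calls"]
    calls_out = calls.reset_index() if len(calls) else pd.DataFrame(columns=["name"])
    write_table(calls_out, outdir / "encroachment_calls.tsv")
    write_table(_matrix_table(det["class_profiles"]).rename(columns={"name": "class"}),
                outdir / "class_profiles.tsv")
    stage_log.append(("encroachment_candidates", len(det["candidates"]), ""))
    stage_log.append(("encroachment_calls", len(calls), ""))

    recovery = None
    if config.ground_truth:
        truth = pd.read_csv(_require(config.ground_truth, "ground truth"), sep="\t")
        truth.columns = [c.lstrip("#") for c in truth.columns]
        if len(calls):
            merged = calls_out.merge(truth[["name", "class"]], on="name",
                                     suffixes=("_called", "_true"))
            merged["correct"] = merged["class_called"] == merged["class_true"]
            recovery = merged
            write_table(merged, outdir / "recovery.tsv")
            acc = merged.loc[merged["class_true"] != "none", "correct"].mean()
            stage_log.append(("recovery_accuracy", round(float(acc), 4) if acc == acc else 0,
                              f"n={len(merged)}"))

    config.to_yaml(outdir / "resolved_config.yaml")
    write_table(pd.DataFrame(stage_log, columns=["stage", "count", "detail"]),
                outdir / "run_summary.tsv")
    return {"dmc": dmc, "dmr": dmr_results, "encroachment": det, "recovery": recovery}


def _read_peak_tier(paths: list[str]) -> list:
    return [read_narrowpeak(_require(p, "narrowPeak")) for p in paths]


def run_chip_pipeline(config: PipelineConfig, outdir) -> dict:
    """Reproducible peaks -> RPKM -> differential calls -> union -> annotation."""
    config.validate()
    if not config.antibodies:
        raise FileNotFoundError("config lists no antibodies")
    genome = read_chrom_sizes(_require(config.chrom_sizes, "chrom.sizes"))
    genes = ann.read_genes_tsv(_require(config.genes, "gene table")) if config.genes else []
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage_log = []
    callsets = []
    per_antibody = {}
    for ab in config.antibodies:
        name = ab["name"]
        atlas_parts = []
        for cond in ("wt", "ko"):
            block = ab[cond]
            fdr50 = _read_peak_tier(block.get("fdr50", []))
            high = _read_peak_tier(block.get("high", []))
            if len(fdr50) >= 2:
                rep = pk.reproducible_peaks(fdr50)
            else:
                # single replicate: only the high-confidence peaks count
                rep = pk.reproducible_peaks(high[:1])
            atlas_parts.append(rep)
            stage_log.append((f"{name}_{cond}_reproducible", len(rep), ""))
        atlas = pk.merge_intervals(pd.concat(atlas_parts, ignore_index=True))
        atlas["Name"] = [f"{name}_peak_{i + 1}" for i in range(len(atlas))]
        write_bed(
            [GenomicInterval(c, int(s), int(e), n) for c, s, e, n in
             zip(atlas["Chromosome"], atlas["Start"], atlas["End"], atlas["Name"])],
            outdir / f"{name}_reproducible.bed", genome,
        )

        frag = {}
        for cond in ("wt", "ko"):
            for i, fp in enumerate(ab[cond].get("fragments", [])):
                frag_df = pd.DataFrame(
                    [(iv.chrom, iv.start, iv.end) for iv in read_bed(_require(fp, "fragments"))],
                    columns=["chrom", "start", "end"],
                )
                frag[f"{cond}_rep{i + 1}"] = frag_df
        wt_samples = {k: v for k, v in frag.items() if k.startswith("wt")}
        ko_samples = {k: v for k, v in frag.items() if k.startswith("ko")}
        if not wt_samples or not ko_samples:
            raise FileNotFoundError(f"antibody {name}: need fragment files for both conditions")
        occ_wt = pk.count_fragments(atlas, wt_samples)
        occ_ko = pk.count_fragments(atlas, ko_samples)
        occ_out = occ_ko.rpkm.add_prefix("ko_").join(occ_wt.rpkm.add_prefix("wt_"))
        occ_out.insert(0, "name", occ_out.index)
        write_table(occ_out.reset_index(drop=True), outdir / f"{name}_rpkm.tsv")

        diff = pk.differential_binding(occ_ko, occ_wt, fc_threshold=config.fc_threshold,
                                       pseudocount=config.pseudocount)
        write_table(diff, outdir / f"{name}_differential.tsv")
        n_up = int((diff["direction"] == "up").sum())
        n_down = int((diff["direction"] == "down").sum())
        stage_log.append((f"{name}_differential", len(diff), f"up={n_up},down={n_down}"))
        callsets.append(diff)
        per_antibody[name] = {"atlas": atlas, "occupancy_wt": occ_wt,
                              "occupancy_ko": occ_ko, "differential": diff}

    union = pk.union_across_antibodies(callsets)
    union_ivs = [
        GenomicInterval(c, int(s), int(e), f"dbr_{i + 1}_{d}")
        for i, (c, s, e, d) in enumerate(
            zip(union["Chromosome"], union["Start"], union["End"], union["direction"])
        )
    ]
    write_bed(union_ivs, outdir / "differential_union.bed", genome)
    stage_log.append(("union_differential", len(union), ""))

    annotated = background = assigned = None
    if genes:
        features = ann.build_context_features(
            genes, genome, promoter_flank=config.promoter_flank,
            distal_extent=config.distal_extent, tes_flank=config.tes_flank,
        )
        annotated = ann.annotate_regions(union_ivs, features)
        write_table(annotated, outdir / "union_annotation.tsv")
        background = ann.background_distribution(genome, features,
                                                 bin_size=config.background_bin)
        write_table(background, outdir / "background_distribution.tsv")
        assigned = ann.assign_genes(union_ivs, features)
        write_table(assigned, outdir / "union_genes.tsv")
        stage_log.append(("annotated_regions", len(annotated), ""))

    config.to_yaml(outdir / "resolved_config.yaml")
    write_table(pd.DataFrame(stage_log, columns=["stage", "count", "detail"]),
                outdir / "run_summary.tsv")
    return {"per_antibody": per_antibody, "union": union, "annotated": annotated,
            "background": background, "genes": assigned}
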