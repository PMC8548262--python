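# Methods

This note documents the models and procedures implemented in
`methencroach`, their assumptions, the parameters that matter, and the
choices made where the procedure left genuine design room.

## Coordinates and input handling

All internal coordinates are 0-based, half-open `[start, end)`.
`methratio`-style CpG tables are treated as 1-based on input
(`one_based=False` disables the shift); the methylation ratio is always
recomputed from the read counts so that `0 ≤ meth ≤ cov`, `cov ≥ 1`
remain verifiable invariants. CpG records on opposite strands of one
symmetric CpG are *not* merged by default; `merge_strands=True` sums
the counts of the `-` record at position p+1 into the `+` record at p.
Whether strand merging should precede analysis is a genuine choice —
it roughly doubles per-site coverage at the cost of masking
strand-specific artefacts — so it is exposed as a reader flag and off
by default.

## Differential methylation (DMC / DMR)

Sites are restricted to coverage ≥ `min_cov` (default 10) in **all**
samples; an absent site counts as coverage 0. Replicate counts are
pooled per condition and each CpG's 2×2 table (methylated /
unmethylated × KO / WT) is tested with a two-sided Fisher's exact
test; Benjamini–Hochberg correction runs over all tested CpGs. A DMC
requires q ≤ `fdr` (0.05) *and* |KO − WT| ≥ `min_diff` (25 percentage
points, on the 0–100 ratio scale). The sign convention is KO − WT
throughout: `hyper` means a methylation gain in the knockout.

Pooling counts (rather than averaging ratios) weights every read
equally, makes the result order-invariant across replicates, and is
the behaviour tested by the single-CpG-region equivalence oracle
(`call_dmr` on single-CpG regions ≡ `call_dmc`). The trade-off is
that between-replicate overdispersion is not modelled; a
replicate-aware logistic model would be the natural extension and the
test statistic is isolated in one function for that purpose.

Region families for DMR calling:

* **CGI** — the input island set;
* **CGI_shore** — 2-kbp flanks, clipped at chromosome ends and
  truncated where they would re-enter a neighbouring island (the
  truncation rule is ours; the flank width is standard);
* **promoter** — TSS ± 2 kbp, symmetric, strand used only to locate
  the TSS;
* **window100/500/1000** — fixed windows sliding by half their size,
  fully inside chromosome bounds.

Region counts are the sums over all surviving CpGs inside the region;
regions with no surviving CpG are reported `untested` rather than
silently dropped.

## Encroachment detection

The detector assumes two conditions with ≥ 1 replicate each and asks
whether methylation invades an island from its ends. Parameters, with
defaults:

| parameter | default | meaning |
|---|---|---|
| `min_cov` | 4 reads | per-replicate coverage for a CpG to qualify |
| `bin_width` | 40 bp | genome tiling for the prefilter, anchored at 0 |
| `min_bins` / `min_increase` | 4 / 0.25 | weak-evidence rule on bin Δ |
| `strong_increase` | 0.50 | at least one bin must gain this much |
| `n_segments` | 40 | per-island profile length, any island size |
| `max_nan` | 30 | NaN cells allowed per differential-matrix row |
| `top_n` | 250 | selection depth per ranking |

Thresholds on bin differences are inclusive (Δ ≥ 0.25 / Δ ≥ 0.50).
Per condition a CpG's level is the unweighted mean of replicate ratios
(`combine="pooled"` switches to pooled-count ratios). Segment
assignment uses exact integer arithmetic,
`floor((pos − start) · n / L)`, so boundary CpGs never depend on
floating-point rounding; a property test checks equality with a
brute-force per-segment membership scan. 5' and 3' are the genomic
left and right ends of the island; the procedure never consults a
hosting gene's strand.

Scores are NaN-ignoring means over segments 1–10, 11–30 and 31–40.
An all-NaN span produces a NaN score and disqualifies the island from
that one ranking only. Rankings are descending with ties broken by
island name, so results are invariant to row order.

**Class assignment.** Selection (union of the three top-`top_n`
lists) says *that* an island encroaches, not *how*. Ranks alone
cannot say how: an island invaded from both ends has 5'- and 3'-end
scores as high as genuinely monodirectional islands, so its end ranks
frequently beat its central rank, and a best-rank rule mislabels a
quarter of bidirectional islands under realistic noise. The default
is therefore a deterministic shape rule on the three scores of each
selected island:

1. if the central score ≥ both end scores → `bidirectional`
   (central or whole-island hypermethylation);
2. else if the weaker end ≥ half the stronger end (and the stronger
   end is positive) → `bidirectional`;
3. else the stronger end's class (`5prime` ties win over `3prime`).

The ½ factor encodes "both ends substantially invaded" without a
per-dataset tunable; on planted data end scores of monodirectional
islands sit near zero (≫ 2 SE below the rule's cut) so the rule is
insensitive to its exact value. `class_rule="best_rank"` restores the
pure rank comparison for users who want it.

## Reproducible peaks and differential occupancy

Replicate agreement uses the relaxed FDR50 tier: the union of all
replicates' FDR50 peaks is merged into maximal coverage-contiguous
intervals (bookended intervals join), and a merged interval is kept
iff at least one of its bases is covered by a peak of *every*
replicate — equivalent to the per-base all-replicate coverage scan the
tests use as oracle, with the merged interval as the reported extent.
With a single replicate the high-confidence set is passed through
unchanged. Fragments count toward a peak with ≥ 1 bp overlap
(half-open; an abutting fragment does not count), the library size is
the total fragment count of the file, and
RPKM = count · 10⁹ / (length · library size). Fold-change is
(mean KO RPKM + c) / (mean WT RPKM + c) with pseudocount c = 0.1 to
keep empty control peaks finite; `up`/`down` require the fold-change
(or its inverse) to exceed the threshold strictly (default 2).
Mean-of-RPKM rather than paired per-replicate ratios keeps the
estimator defined for unequal replicate numbers. The per-antibody
union merges up- and down-regulated intervals separately.

## Genomic-context annotation

Features are built per gene, pooled across isoforms, strand-aware for
"upstream"/"downstream": promoter halves of 2 kbp on each side of the
TSS; distal features reach 50 kbp but start where the promoter ends;
exons and their gap introns; a TES window of ± 2 kbp (the feature list
names TES without a width, so the width is ours and configurable).
Overlaps *between* classes are resolved purely by the priority order,
a region taking the first class it touches by ≥ 1 bp and `Intergenic`
otherwise — so labelling is a partition and removing lower-priority
features never changes a label. The background distribution annotates
a 1-kbp tiling of the genome (trailing partial bins included) with the
same rule. Gene assignment is independent of the label: a region is
associated with every gene whose promoter (either half) it overlaps,
possibly several, possibly none.

## Synthetic data

The methylome generator emulates the statistical structure the
detector assumes, not sequence realism. A genome of
`n_chromosomes × chromosome_length` carries non-overlapping islands
(600–1200 bp, ≥ 2.5 kbp apart) with CpGs every 10 bp inside islands
and every 150 bp outside; WT methylation is 0.05 inside islands and
0.8 outside. For each CpG and sample, coverage ~ Poisson(30) (zero →
the record is absent, mirroring absent `methratio` rows) and the
methylated count ~ Binomial(coverage, p). In the knockout, planted
islands raise p by an encroachment front: a linear ramp from depth
Δ = 0.5 at the invaded edge to 0 at `extent` = 50 % of the island
length; `bidirectional` applies both ramps (point-wise maximum),
`full` raises the whole island uniformly. The default cohort is 200
unaffected islands plus 20 per planted class, two replicates per
condition — the standard recovery experiment the acceptance script
re-runs. Class sizes are given as integer counts (`class_counts`)
rather than proportions so cohorts are exact.

The peak generator plants true peaks present in every replicate's
FDR50 tier (edges jittered up to 50 bp), decoy peaks private to one
replicate, and per-peak fragment counts ~ Poisson(200 · FC in the
knockout) with FC ∈ {4, 1, ¼}, plus uniform background fragments.

Every random draw comes from a stream keyed by (seed, sample,
chromosome) via `SeedSequence`, so outputs are byte-identical across
runs and adding a replicate or chromosome never perturbs existing
ones.

**What passing these tests does and does not show.** The generator
draws independent binomial counts at fixed spacing; real WGBS has
correlated neighbouring CpGs, coverage biases, bisulfite conversion
failure and strand asymmetries, and real ChIP-seq has non-uniform
background and fragment-length structure. Recovery results on this
cohort demonstrate the algorithmic correctness and calibration of the
pipeline under its own sampling model, not performance on real
libraries.

## Numerical and degenerate-input choices

* NaN is the universal "no data" marker; NaN-ignoring means are used
  exactly where the procedure says missing segments are tolerated.
  Tables serialise NaN as the literal string `NaN`.
* Benjamini–Hochberg may reorder p-values; q is only guaranteed in
  [0, 1].
* Empty inputs: a region family with no regions errors; a region with
  no CpGs is `untested`; an island cohort where nothing passes the
  prefilter yields empty outputs with a warning rather than an error;
  an empty fragment file is a zero library and errors.
* Problem sizes in tests and the acceptance script (two ~0.7-Mbp
  chromosomes, 260 islands, 10⁴ CpGs, tens of peaks) were chosen so
  the binomial/Poisson standard errors are several times smaller than
  the effects being recovered; larger simulations sharpen nothing the
  assertions measure.

## Known limitations

* The Fisher test on pooled counts ignores between-replicate
  overdispersion; with many replicates a beta-binomial or logistic
  model would be preferable.
* The encroachment prefilter's absolute thresholds (0.25 / 0.50)
  implicitly assume a near-unmethylated WT island; islands already
  half-methylated in WT cannot show a 0.5 gain.
* Annotation assumes the simplified gene table (one transcript per
  row); GTF attribute parsing is out of scope.
* BAM/FASTQ/bigWig handling is out of scope: alignment-level
  processing and peak calling are upstream of this package.
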