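# Methods

## Scope and data model

`crelink` annotates noncoding GWAS variants with the cell types and target
genes through which they plausibly act. It consumes per-sample H3K27ac peak
calls with fragment counts, a tag-SNP catalog, per-population pairwise LD
tables, sparse intra-chromosomal contact matrices at 5 kb resolution, a
TSS annotation, and a cell-labeled single-cell count matrix. Intervals are
0-based half-open internally; printed coordinates are 1-based inclusive;
SNP positions are 1-based. Raw-read processing (alignment, peak calling,
Hi-C pair filtering) and single-cell clustering/label assignment are out of
scope — labels and peak calls are inputs.

## cRE catalog

Peaks within 2.5 kb of a TSS are removed (a peak is dropped iff a TSS lies
in `[start − 2500, end + 2500)`, i.e. distance is measured to the peak
*edge*, and exactly 2.5 kb counts as proximal). Remaining peaks are unioned
across samples and stitched: intervals with gap ≤ 3000 bp (inclusive
boundary; the stitch rule is stated as "within 3 kb" so the tie goes to
joining) are merged. Stitched cREs are not re-checked against TSS distance.
Fragment counts are aggregated onto cREs by ≥ 1 bp interval overlap,
converted to RPM (count / library size × 10⁶) and quantile-normalized:
each column is replaced by the across-column mean of order statistics at
its ranks; ties share the mean of their reference values. With ties this
dialect (the common `ties="average"` behavior) trades exact multiset
identity across columns for rank stability; tie-free columns end up with
identical sorted values.

## Cell-type-specific cREs

For each cRE and cell type we test *elevated* activity (one-sided) in that
type versus all remaining samples on log2(RPM + 1). The per-cRE residual
variance from the one-way cell-type layout (df = n − k) is shrunk by
empirical Bayes: a scaled inverse-chi-square prior is fitted to the observed
variances by matching the moments of log s² (trigamma inversion by Newton
iteration), giving posterior variances `(d₀s₀² + df·s²)/(d₀ + df)` and a
moderated t with df + d₀ degrees of freedom. This stabilises the 2–3
replicate design the same way moderated linear-model testing does in
expression analysis; the original study used a count-model quasi-likelihood
F test, and this module implements the same contract (calibrated one-vs-rest
with moderated dispersion) rather than that package's internals. P-values
are BH-adjusted per cell type across cREs; a cRE is labeled with the type of
its minimum q when q < α (default 0.05), ties broken toward the larger mean
activity, otherwise "constitutive". Zero-variance rows with zero contrast
return p = 1 and are never called.

Row z-scores use the population (n-denominator) SD, so a profile positive
in exactly one of six cell types scores √5 ≈ 2.236 in that type and
−1/√5 ≈ −0.447 elsewhere; constant rows map to zeros.

## LD expansion

A proxy joins a tag's expanded set iff r² > 0.8 (strict; the boundary value
is excluded) with that tag in ≥ 3 population panels. LD tables are
symmetrized and deduplicated keeping the max r² per (population, pair).
The tag itself is always a member of its own set; a SNP in LD with two tags
yields two records (one per parent); there is no transitive expansion and
no distance window (none is specified for the procedure). Every record
carries its parental tag, supporting-population count and per-population r².

## Contact calling

Only intra-chromosomal pairs with 15 kb ≤ d ≤ 1 Mb are tested (self-pairs
and sub-15 kb pairs mirror the short-range artifact removal of Hi-C
preprocessing). The expected count μ(d) is the stratum mean over *all*
possible bin pairs at distance d — structural zeros included — smoothed to
be non-increasing in d by pool-adjacent-violators (weights = pairs per
stratum) because raw long-range stratum means are noisy; empty strata get a
half-count floor so μ > 0. Each pair is scored with the Poisson upper tail
P(X ≥ observed | μ(d)) and BH-adjusted against the full per-chromosome
universe of tested pairs (zero-count pairs have p = 1 and enter the
universe size only); Q < 0.01 defines significance. The Poisson tail
replaces the original spline-refinement contact caller with a deterministic,
desk-scale equivalent of its contract (distance-conditioned expectation +
upper-tail test + BH); discreteness makes it mildly conservative, which the
null calibration test verifies. Raw counts are used (no matrix balancing).

A gene's promoter anchors bin b iff its TSS lies within 2.5 kb of the bin
interval (`b·res − w ≤ tss < (b+1)·res + w`). The TSS is the
strand-resolved transcription start (for minus-strand annotations the
reader takes the annotated end); downstream code is strand-agnostic.
Contacts anchoring two promoters yield one record per gene. Union across
cell lines is keyed by (gene, distal bin) with the supporting cell-line set
recorded; it is idempotent and order-invariant.

## Integration

SNP–cRE containment is 1-based inclusive on both ends (matching printed
coordinates). A tag is "linked" iff any of its expanded SNPs (itself
included) falls in a cRE; a tag with both specific and constitutive
associations counts as specific-linked, and "constitutive-only" is the
complement. Percentages are rounded half-up to two decimals. Target genes
of a SNP-harboring specific cRE are all genes whose union-set promoter
interaction has a distal bin overlapping the cRE by ≥ 1 bp. Report rows are
ordered by descending per-cell-type row count, then cell type, locus and
tag, which fixes the layout deterministically.

## Single-cell profiles

Cells expressing < 200 genes (count > 0 defines "expressed") or with
mitochondrial count fraction > 20% are discarded; both thresholds are
boundary-exclusive for removal, so 200 genes / exactly 20% are retained.
Counts are normalized per cell to 10,000 and natural-log transformed
(`ln(1 + c/total × 10⁴)` — the conventional dialect of the standard
single-cell toolchain; the procedure names total-count normalization and
log transform without constants). Per-gene cell-type means are z-scored
across types with the population SD. Six report columns (Myeloid, B cell,
T cell, Epithelial, Fibroblast, Endothelial) reproduce the √5 one-hot
ceiling; the simulator's eight types (adding NK and Cancer) are supported
throughout and the column set is configurable.

## Enrichment statistic

"Relative expression" of a target set is taken as the mean over deduplicated
(gene, assigned type) pairs of z[gene, type] — an interpretation consistent
with the z-representation of the target tables, adopted because no closed
formula is stated for the axis it summarizes. The null resamples |targets|
genes uniformly without replacement from all profiled genes, keeping the
assigned-type multiset; p = (1 + #{null ≥ observed}) / (1 + N), never zero.
Null sets are size- and type-matched but not expression-matched (no matching
is described). The per-type Fisher exact table is {target genes of the type,
all other profiled genes} × {max-z column equals the type, otherwise}, with
the conventional two-sided exact p (sum of table probabilities ≤ the
observed table's); exact max-z ties count as "top". One seeded generator
drives the resampling and the seed is reported with the result.

## Synthetic study design

The generator plants the only structure in the data; shuffled labels reduce
every recovery metric to chance. Defaults (one `SimConfig`, seed-determined
byte-identical outputs via independent child streams per stage):

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 8 Mb | synthetic chromosomes chrS1, chrS2 |
| n_cell_types / samples_per_type | 8 / 3 | study-like design (24 samples) |
| n_cres / frac_specific / specific_fold | 300 / 0.4 / 8 | planted cREs; 120 one-type-specific |
| peak_base_mean / nb_dispersion | 50 / 0.1 | negative-binomial fragment counts |
| n_tags / n_populations / ld_r2_high | 30 / 5 / 0.9 | tag catalog; proxies recur in ≥ 3 panels, decoys in exactly 2 |
| hic_base / decay_exponent | 200 / 1.0 | μ(k) = 200·k⁻¹ Poisson background per 5 kb bin distance k |
| loop_fold / loop_dist_range | 10 / 30–250 kb | planted loops, each in 2 of 4 cell lines |
| n_cells_per_type / expr_fold / frac_mito | 60 / 8 / 0.05 | single-cell matrix; planted one-type genes |
| frac_qc_bad | 0.05 | *deliberate* QC violators (150-gene cells; 30%-mito cells) |

Genes sit every 20 kb; planted cREs occupy 4–8 kb downstream of a host TSS
(width 1–2 kb), which keeps them distal after ±200 bp peak jitter and > 3 kb
apart so merging preserves them 1:1. Tag SNPs sit 5 kb upstream of host
TSSs, outside every cRE; planted proxies fall inside their cRE, decoy and
unlinked proxies outside or rejected by the recurrence rule. Loop targets
are drawn per SNP-harboring specific cRE from same-chromosome TSSs at
30–250 kb; the upper bound (inside the allowed 30 kb–1 Mb window) together
with `hic_base = 200` keeps the worst-case planted pair (μ ≈ 3.3, loop mean
≈ 33) detectable at Q < 0.01 against the ≈ 3 × 10⁵-pair per-chromosome BH
universe with negligible miss probability — a power choice made at design
time so the recovery suite measures correctness, not luck. Loop target
genes are elevated `expr_fold`-fold in the loop's cell type in the
single-cell matrix, plus eight extra planted marker genes per type.

What the generator does **not** emulate: read-level noise, peak-calling
artifacts, copy-number or mappability biases in contact maps, inter-
chromosomal contacts, LD block structure beyond direct tag–proxy pairs,
doublets and ambient RNA. Passing recovery tests therefore demonstrates
the pipeline's logic and calibration under its stated noise model, not
performance on real sequencing data.

## Problem sizes and calibration tolerances

Test and driver runs use the default desk-scale study (2 × 8 Mb genome,
≈ 3 × 10⁵ tested pairs per chromosome per cell line, 480 cells); null
calibrations use a 2 × 4 Mb variant with all fold changes at 1. The
contact-caller check requires the significant fraction ≤ 0.01 + 3·SE under
the loop-free model. The specificity type-I check compares the rejection
rate at p < 0.05 under permuted labels within 3 cluster-robust SEs — the
eight one-vs-rest p-values of one cRE share samples, so the Monte-Carlo
error is computed over per-cRE rejection fractions rather than by the naive
binomial formula. Permutation-p uniformity is asserted as a seed-sweep mean
in [0.4, 0.6] at N = 199. Recovery thresholds (≥ 90% of planted links, zero
unplanted genes, permutation p ≤ 0.001) run at fixed seeds recorded in the
test suite.

## Known limitations

* The moderated-t specificity test operates on normalized log intensities,
  not raw counts; with very low counts a count model would be preferable.
* μ(d) pools whole chromosomes; locus-specific coverage biases (visible in
  real Hi-C) are not modeled, so on real data the caller should be fed
  balanced matrices or a refined background.
* The enrichment null is not expression-matched; highly expressed gene
  classes could inflate significance on real data.
* Quantile normalization assumes comparable global signal distributions
  across samples; it will mask genuine global activity differences.
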