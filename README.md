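# crelink

Cell-type-resolved functional annotation of GWAS risk variants for lung
cancer-style studies. Most genome-wide-significant variants fall in noncoding
DNA; `crelink` implements the integrative procedure that interprets them:

1. **cRE catalog** — from per-sample H3K27ac peak calls, keep peaks distal to
   promoters (> 2.5 kb from any TSS), merge across samples, stitch peaks
   within 3 kb, and quantify activity as quantile-normalized RPM
   (reads per million) per cis-regulatory element (cRE).
2. **Cell-type specificity** — one-vs-rest test per cRE and cell type on
   log2(RPM+1) with empirical-Bayes moderated variance, Benjamini–Hochberg
   FDR < 0.05; each cRE gets one cell-type label or "constitutive".
3. **LD expansion** — GWAS tag SNPs are expanded to proxies with r² > 0.8
   recurrent in ≥ 3 of 5 population panels, each proxy traceable to its
   parental tag.
4. **Chromatin contacts** — 5 kb intra-chromosomal bin pairs within 1 Mb are
   tested against a monotone distance-decay expectation μ(d) (Poisson upper
   tail, BH per chromosome, Q < 0.01); significant contacts are anchored to
   promoters (TSS within 2.5 kb of a bin) and unioned across cell lines.
5. **Integration** — expanded SNPs are intersected with the cRE catalog
   (1-based inclusive containment), tags roll up into specific / constitutive
   classes, and each SNP-harboring specific cRE is linked to every gene whose
   promoter it contacts.
6. **Expression enrichment** — from a QC-filtered (≥ 200 expressed genes,
   ≤ 20% mitochondrial counts), log-normalized single-cell matrix, per-gene
   cell-type mean profiles are z-scored with the population (n-denominator)
   SD; the mean assigned-type z of target genes is compared with N = 100,000
   size- and type-matched random gene sets (add-one empirical p), plus
   per-type Fisher exact tests.

A synthetic-data generator (`crelink.simulate`) produces every input with
planted ground truth — specific cREs, LD proxies and decoys, promoter-cRE
loops on a distance-decay background, and cell-type-structured single-cell
counts — so the whole pipeline is testable end to end without downloads.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on the default
synthetic study (seed 1) and write their tables under `results/`:

```bash
cd analysis
python 01_simulate.py && python 06_link_targets.py && python 07_expression_enrichment.py
```

`06_link_targets.py` prints the linkage summary:

```json
{
  "n_tags": 30,
  "n_linked": 16,
  "n_specific_linked": 10,
  "n_constitutive_only": 6,
  "pct_linked": 53.33,
  "planted_links": 10,
  "recovered_links": 10,
  "unplanted_links": 0
}
```

16 of the 30 simulated tag SNPs have an LD-expanded SNP inside a cRE
(53.33%); 10 of those hit cell-type-specific cREs, and every one of the 10
planted cRE→gene loops is recovered through a significant chromatin contact
with no spurious target genes. `07_expression_enrichment.py` then reports

```json
{
  "observed_mean_assigned_z": 2.5954,
  "permutations": 99999,
  "empirical_p": 1e-05
}
```

i.e. the inferred target genes sit near the one-type-expression ceiling
(z = √5 ≈ 2.236 for a one-hot profile over six cell types; higher over
eight) and no random gene set of the same size and type composition matched
them in 10⁵ draws.

## Layout

```
src/crelink/        library: simulate, catalog, specificity, ld, contacts,
                    integration, scexpr, enrichment, pipeline
src/crelink/data/   packaged reference tables (annotated SNPs, target genes,
                    cell-population marker genes)
analysis/           numbered drivers writing tables under results/
tests/              unit, property and acceptance suites
docs/methods.md     model, parameter and calibration notes
```
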