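"""End-to-end orchestration of the annotation pipeline on a simulated study.

Chains the stages exactly as the analysis drivers do: build the distal cRE
catalog from per-sample peaks, call cell-type-specific cREs, LD-expand the
tag catalog, call significant promoter-anchored contacts per cell line and
union them, intersect SNPs with cREs, infer target genes, profile single-cell
expression, and test target-gene enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import catalog as cat
from . import contacts as ctc
from . import enrichment as enr
from . import integration as itg
from . import ld as ldx
from . import scexpr as sce
from . import specificity as spc
from .simulate import SimResult


@dataclass
class PipelineResult:
    catalog: cat.CreCatalog
    pvals: pd.DataFrame
    qvals: pd.DataFrame
    calls: pd.DataFrame
    expanded: pd.DataFrame
    significant: dict  # cell_line -> significant-contact DataFrame
    union: pd.DataFrame
    associations: pd.DataFrame
    rollup: dict
    targets: pd.DataFrame
    means: pd.DataFrame
    z: pd.DataFrame
    enrichment: enr.EnrichmentResult | None = None
    extras: dict = field(default_factory=dict)


def build_catalog(sim: SimResult, min_dist: int = 2500, stitch: int = 3000) -> cat.CreCatalog:
    tss = sim.genes[["gene_id", "chrom", "tss"]]
    filtered = {
        sid: cat.filter_distal(df, tss, min_dist=min_dist) for sid, df in sim.peaks.items()
    }
    intervals = cat.merge_and_stitch(list(filtered.values()), stitch=stitch)
    catalog = cat.CreCatalog(cres=intervals, sample_meta=sim.sample_meta)
    counts = cat.count_in_cres(catalog, sim.peaks)
    rpm = cat.quantify_rpm(counts, sim.library_sizes)
    catalog.activity = cat.quantile_normalize(rpm)
    catalog.normalized = True
    return catalog


def call_contacts(sim: SimResult, q_thresh: float = 0.01):
    """Per-line significant contacts and the union promoter-interaction set."""
    tss = sim.genes[["gene_id", "chrom", "tss"]]
    res = sim.config.resolution
    per_line_sig: dict[str, list] = {}
    for (line, _chrom), cm in sim.contact_matrices.items():
        sig = ctc.call_significant(cm, q_thresh=q_thresh)
        per_line_sig.setdefault(line, []).append(sig)
    significant = {
        line: pd.concat(frames, ignore_index=True) for line, frames in per_line_sig.items()
    }
    anchored = [
        ctc.anchor_promoters(df, tss, resolution=res) for df in significant.values()
    ]
    union = ctc.union_interactions(anchored)
    return significant, union


def profile_expression(sim: SimResult):
    adata = sce.qc_filter(sim.adata)
    adata = sce.normalize_log(adata)
    means = sce.celltype_means(adata, cell_types=list(sim.config.cell_types))
    z = sce.profile_z(means)
    return means, z


def run_pipeline(
    sim: SimResult,
    alpha: float = 0.05,
    q_thresh: float = 0.01,
    r2_min: float = 0.8,
    min_pops: int = 3,
    n_iterations: int = 9999,
    seed: int = 0,
) -> PipelineResult:
    catalog = build_catalog(sim)
    labels = sim.sample_meta.set_index("sample_id")["cell_type"]
    pvals = spc.one_vs_rest_test(catalog.activity, labels)
    qvals = spc.fdr_by_type(pvals)
    calls = spc.classify_specific(qvals, catalog.activity, labels, alpha=alpha)
    expanded = ldx.expand_tags(sim.tags, sim.ld, r2_min=r2_min, min_pops=min_pops)
    significant, union = call_contacts(sim, q_thresh=q_thresh)
    associations = itg.overlap_snps_cres(expanded, catalog, calls)
    rollup = itg.tag_rollup(associations, sim.tags)
    targets = itg.infer_targets(associations, union, resolution=sim.config.resolution)
    means, z = profile_expression(sim)
    enrichment = None
    if len(targets):
        enrichment = enr.permutation_test(targets, z, n_iterations=n_iterations, seed=seed)
    return PipelineResult(
        catalog=catalog,
        pvals=pvals,
        qvals=qvals,
        calls=calls,
        expanded=expanded,
        significant=significant,
        union=union,
        associations=associations,
        rollup=rollup,
        targets=targets,
        means=means,
        z=z,
        enrichment=enrichment,
    )


# ---------------------------------------------------------------------------
# ground-truth comparison helpers (used by tests and the recovery analyses)


def match_catalog_to_truth(catalog: cat.CreCatalog, truth) -> dict:
    """Map planted cRE ids to catalog cre_ids by >= 1 bp interval overlap."""
    mapping = {}
    index = catalog.interval_index()
    for rec in truth.cre_intervals.itertuples(index=False):
        idx = index.get(rec.chrom)
        if idx is None:
            continue
        starts, ends, ids = idx
        import numpy as np

        first = int(np.searchsorted(ends, rec.start, side="right"))
        if first < len(starts) and starts[first] < rec.end:
            mapping[rec.planted_id] = ids[first]
    return mapping


def specificity_recall_precision(calls: pd.DataFrame, catalog: cat.CreCatalog, truth) -> dict:
    """Recall/precision of specific-cRE calls against the planted labels."""
    mapping = match_catalog_to_truth(catalog, truth)
    planted = {
        mapping[pid]: label
        for label, pids in truth.specific_cres.items()
        for pid in pids
        if pid in mapping
    }
    called = calls[calls["cell_type"] != spc.CONSTITUTIVE]
    called_map = dict(zip(called["cre_id"], called["cell_type"]))
    tp = sum(1 for cre, lab in planted.items() if called_map.get(cre) == lab)
    recall = tp / len(planted) if planted else float("nan")
    precision = tp / len(called_map) if called_map else float("nan")
    return {"recall": recall, "precision": precision, "n_planted": len(planted), "n_called": len(called_map)}
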