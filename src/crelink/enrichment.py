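"""Expression enrichment of inferred target genes in their assigned cell types.

The test statistic is the mean, over (gene, cell type) target assignments,
of the gene's z-scored expression in its assigned type. Its null is built
by Monte-Carlo resampling: size-matched gene sets drawn uniformly without
replacement from the profiled universe, keeping the assigned-type multiset,
with an add-one empirical p-value. Per cell type, a two-sided Fisher exact
test asks whether target genes are over-represented among genes whose
maximal z lies in that type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    observed: float
    n_iterations: int
    n_null_ge: int
    p: float
    seed: int


@dataclass
class FisherResult:
    cell_type: str
    table: np.ndarray  # 2x2: rows target/non-target, cols top-in-type/not
    p: float


def _target_pairs(targets: pd.DataFrame, z: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated (gene_id, cell_type) pairs restricted to profiled genes."""
    pairs = targets[["gene_id", "cell_type"]].drop_duplicates()
    missing = sorted(set(pairs["gene_id"]) - set(z.index))
    if missing:
        warnings.warn(f"{len(missing)} target gene(s) absent from profile, dropped: {missing[:5]}")
        pairs = pairs[pairs["gene_id"].isin(z.index)]
    bad_types = sorted(set(pairs["cell_type"]) - set(z.columns))
    if bad_types:
        raise ValueError(f"assigned cell types absent from z profile: {bad_types}")
    return pairs.reset_index(drop=True)


def observed_statistic(targets: pd.DataFrame, z: pd.DataFrame) -> float:
    """Mean z of target genes in their assigned cell types."""
    pairs = _target_pairs(targets, z)
    if not len(pairs):
        raise ValueError("empty target set")
    vals = [z.at[g, t] for g, t in zip(pairs["gene_id"], pairs["cell_type"])]
    return float(np.mean(vals))


def permutation_test(
    targets: pd.DataFrame,
    z: pd.DataFrame,
    n_iterations: int = 100_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Monte-Carlo null of the mean assigned-type z statistic.

    Each iteration draws |targets| genes uniformly *without replacement* from
    all profiled genes and pairs them with the observed assigned-type
    multiset. p = (1 + #null >= observed) / (1 + N); never zero.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    pairs = _target_pairs(targets, z)
    n = len(pairs)
    if n == 0:
        raise ValueError("empty target set")
    universe = z.index.to_numpy()
    if len(universe) < n:
        raise ValueError(f"gene universe ({len(universe)}) smaller than target set ({n})")
    obs = observed_statistic(targets, z)
    type_cols = np.array([z.columns.get_loc(t) for t in pairs["cell_type"]])
    zmat = z.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    g_total = len(universe)
    count_ge = 0
    chunk = max(1, min(n_iterations, 20_000))
    done = 0
    while done < n_iterations:
        m = min(chunk, n_iterations - done)
        # uniform without-replacement samples, randomly ordered per row
        keys = rng.random((m, g_total))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        idx = rng.permuted(idx, axis=1)
        stat = zmat[idx, type_cols[None, :]].mean(axis=1)
        count_ge += int((stat >= obs).sum())
        done += m
    p = (1 + count_ge) / (1 + n_iterations)
    return EnrichmentResult(observed=obs, n_iterations=n_iterations, n_null_ge=count_ge, p=p, seed=seed)


def top_type(z: pd.DataFrame) -> pd.Series:
    """Cell type of each gene's maximal z (first column on exact ties)."""
    return z.idxmax(axis=1)


def count_top_in_type(targets: pd.DataFrame, z: pd.DataFrame) -> pd.Series:
    """Per cell type, number of target genes whose max z is in their assigned type.

    Exact ties on the maximum count as top. Returns a Series indexed by the
    z profile's cell types (zero-filled).
    """
    counts = pd.Series(0, index=z.columns, dtype=int)
    if not len(targets):
        return counts
    pairs = _target_pairs(targets, z)
    for g, t in zip(pairs["gene_id"], pairs["cell_type"]):
        row = z.loc[g]
        if z.at[g, t] == row.max():
            counts[t] += 1
    return counts


def fisher_specificity(targets: pd.DataFrame, z: pd.DataFrame, cell_type: str) -> FisherResult:
    """Two-sided Fisher exact test of target over-representation in a type.

    2x2 table: rows = {target genes of this type, all other profiled genes},
    columns = {gene's max-z column equals this type, otherwise}.
    """
    pairs = _target_pairs(targets, z)
    tgenes = set(pairs.loc[pairs["cell_type"] == cell_type, "gene_id"])
    if not tgenes:
        raise ValueError(f"no target genes assigned to cell type {cell_type!r}")
    zmax = z.max(axis=1)
    is_top = (z[cell_type] == zmax).to_numpy()
    is_target = z.index.isin(tgenes)
    a = int((is_target & is_top).sum())
    b = int((is_target & ~is_top).sum())
    c = int((~is_target & is_top).sum())
    d = int((~is_target & ~is_top).sum())
    table = np.array([[a, b], [c, d]])
    if min(table.sum(axis=0)) == 0 or min(table.sum(axis=1)) == 0:
        warnings.warn("degenerate 2x2 margins; Fisher p set to 1")
        return FisherResult(cell_type=cell_type, table=table, p=1.0)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return FisherResult(cell_type=cell_type, table=table, p=p)
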