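"""Significant chromatin-contact calling against a distance-decay background.

Intra-chromosomal 5 kb bin-pair counts are tested within a 1 Mb window.
The expected count at bin distance d is the mean observed count over *all*
possible bin pairs at that distance (structural zeros included), smoothed to
be non-increasing in d by pool-adjacent-violators. Each pair is then scored
with an upper-tail Poisson p-value and Benjamini-Hochberg adjusted over the
full per-chromosome universe of tested pairs; Q < 0.01 defines significant
contacts. Self pairs and pairs closer than 15 kb are never tested.

Significant contacts are anchored to gene promoters (TSS within 2.5 kb of a
bin) and combined across cell lines as a union set with support tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression

from .specificity import bh_fdr  # noqa: F401  (re-exported convenience)

DEFAULT_RESOLUTION = 5000
MIN_DIST = 15_000
MAX_DIST = 1_000_000


class ContactError(ValueError):
    pass


@dataclass
class ContactMatrix:
    """Sparse intra-chromosomal contact counts for one cell line."""

    cell_line: str
    chrom: str
    chrom_length: int
    triplets: pd.DataFrame  # bin_i, bin_j, count with i <= j
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self):
        if self.resolution <= 0 or self.chrom_length <= 0:
            raise ContactError("resolution and chromosome length must be positive")
        t = self.triplets
        if len(t) and ((t["count"] < 0).any() or (t["bin_i"] > t["bin_j"]).any()):
            raise ContactError("triplets must have count >= 0 and bin_i <= bin_j")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.resolution)


def _dist_range(resolution: int, n_bins: int, min_dist: int = MIN_DIST, max_dist: int = MAX_DIST):
    kmin = -(-min_dist // resolution)  # smallest tested bin distance
    kmax = min(max_dist // resolution, n_bins - 1)
    return kmin, kmax


def expected_decay(
    matrix: ContactMatrix, max_dist: int = MAX_DIST, min_dist: int = MIN_DIST
) -> pd.DataFrame:
    """Distance-stratified expected counts mu(d), monotone non-increasing.

    Returns DataFrame(k, distance, n_pairs, mu) for bin distances k in the
    tested window. The stratum mean divides the total observed count by the
    number of *possible* pairs at that distance, so unobserved pairs count
    as zeros.
    """
    if not len(matrix.triplets):
        raise ContactError("empty contact matrix")
    n = matrix.n_bins
    res = matrix.resolution
    kmin, kmax = _dist_range(res, n, min_dist, max_dist)
    if kmax < kmin:
        raise ContactError("no testable distance strata for this chromosome")
    t = matrix.triplets
    k = (t["bin_j"] - t["bin_i"]).to_numpy()
    in_win = (k >= kmin) & (k <= kmax)
    ks = np.arange(kmin, kmax + 1)
    sums = np.bincount(k[in_win] - kmin, weights=t["count"].to_numpy()[in_win], minlength=len(ks))
    n_pairs = (n - ks).astype(float)
    raw = sums / n_pairs
    iso = isotonic_regression(raw, weights=n_pairs, increasing=False)
    mu = np.asarray(iso.x, dtype=float)
    # keep mu strictly positive: empty tail strata get half a pseudo-count
    floor = 0.5 / n_pairs
    mu = np.maximum(mu, floor)
    return pd.DataFrame({"k": ks, "distance": ks * res, "n_pairs": n_pairs.astype(int), "mu": mu})


def call_significant(
    matrix: ContactMatrix,
    decay: pd.DataFrame | None = None,
    q_thresh: float = 0.01,
    max_dist: int = MAX_DIST,
    min_dist: int = MIN_DIST,
) -> pd.DataFrame:
    """Poisson upper-tail test of every in-window pair, BH over the chromosome.

    The multiple-testing universe is every possible pair in the window; pairs
    with zero observed count have p = 1 and can never be significant, so only
    nonzero pairs are materialized. Returns the retained (q < q_thresh)
    contacts with observed, expected, distance, p and q columns.
    """
    if decay is None:
        decay = expected_decay(matrix, max_dist=max_dist, min_dist=min_dist)
    n = matrix.n_bins
    kmin, kmax = _dist_range(matrix.resolution, n, min_dist, max_dist)
    mu_by_k = decay.set_index("k")["mu"]
    t = matrix.triplets
    k = (t["bin_j"] - t["bin_i"]).to_numpy()
    obs = t["count"].to_numpy()
    if (obs < 0).any():
        raise ContactError("negative observed counts")
    sel = (k >= kmin) & (k <= kmax) & (obs > 0)
    sub = t[sel].copy()
    ksel = k[sel]
    missing = np.setdiff1d(np.unique(ksel), mu_by_k.index.to_numpy())
    if missing.size:
        raise ContactError(f"decay expectation missing for bin distances {missing.tolist()}")
    mu = mu_by_k.to_numpy()[np.searchsorted(mu_by_k.index.to_numpy(), ksel)]
    p = stats.poisson.sf(sub["count"].to_numpy() - 1, mu)
    m_universe = int((n - np.arange(kmin, kmax + 1)).sum())
    # BH step-up against the full universe; the implicit p=1 zero-count pairs
    # rank last and cannot change the cummin below.
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_universe / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    sub["observed"] = sub.pop("count")
    sub["expected"] = mu
    sub["distance"] = ksel * matrix.resolution
    sub["p"] = p
    sub["q"] = q
    sub["cell_line"] = matrix.cell_line
    sub["chrom"] = matrix.chrom
    keep = sub[sub["q"] < q_thresh].reset_index(drop=True)
    return keep[["cell_line", "chrom", "bin_i", "bin_j", "observed", "expected", "distance", "p", "q"]]


def promoter_bins(tss: pd.DataFrame, resolution: int, window: int = 2500) -> pd.DataFrame:
    """All (chrom, bin, gene_id) whose bin lies within ``window`` of the TSS.

    A TSS at position t anchors bin b iff b*res - window <= t < (b+1)*res + window.
    """
    rows = []
    for gene, chrom, t in tss[["gene_id", "chrom", "tss"]].itertuples(index=False):
        b_lo = (int(t) - window) // resolution
        b_hi = (int(t) + window) // resolution
        for b in range(max(b_lo, 0), b_hi + 1):
            rows.append((chrom, b, gene))
    return pd.DataFrame(rows, columns=["chrom", "bin", "gene_id"])


def anchor_promoters(
    contacts: pd.DataFrame,
    tss: pd.DataFrame,
    resolution: int = DEFAULT_RESOLUTION,
    window: int = 2500,
) -> pd.DataFrame:
    """Promoter-anchored interactions from significant contacts.

    Each contact yields one record per (gene, anchoring end): the end whose
    bin lies within ``window`` bp of the gene's TSS is the promoter bin, the
    other end the distal bin. A contact joining two promoters yields records
    for both genes.
    """
    pb = promoter_bins(tss, resolution, window)
    key = pb.set_index(["chrom", "bin"])["gene_id"]
    gene_map: dict[tuple, list] = {}
    for (chrom, b), gene in key.items():
        gene_map.setdefault((chrom, b), []).append(gene)
    rows = []
    for rec in contacts.itertuples(index=False):
        for prom, distal in ((rec.bin_i, rec.bin_j), (rec.bin_j, rec.bin_i)):
            for gene in gene_map.get((rec.chrom, prom), ()):
                rows.append(
                    (
                        rec.cell_line,
                        rec.chrom,
                        gene,
                        prom,
                        distal,
                        abs(rec.bin_j - rec.bin_i) * resolution,
                    )
                )
    return pd.DataFrame(
        rows, columns=["cell_line", "chrom", "gene_id", "promoter_bin", "distal_bin", "distance"]
    )


def union_interactions(per_line: list[pd.DataFrame], resolution: int | None = None) -> pd.DataFrame:
    """Union of promoter interactions across cell lines, keyed (gene, distal bin).

    Records the supporting cell-line set per interaction. Inputs must share
    one binning resolution (enforced when ``resolution`` columns are present).
    """
    frames = [df for df in per_line if len(df)]
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "gene_id", "distal_bin", "support", "n_support", "distance"]
        )
    if resolution is not None:
        for df in frames:
            if "resolution" in df.columns and not (df["resolution"] == resolution).all():
                raise ContactError("resolution mismatch across cell lines")
    allc = pd.concat(frames, ignore_index=True)
    grouped = allc.groupby(["chrom", "gene_id", "distal_bin"], as_index=False).agg(
        support=("cell_line", lambda s: ",".join(sorted(set(s)))),
        n_support=("cell_line", lambda s: len(set(s))),
        distance=("distance", "min"),
    )
    return grouped.sort_values(["chrom", "gene_id", "distal_bin"]).reset_index(drop=True)


def distance_summary(contacts_by_line: dict[str, pd.DataFrame]) -> pd.Series:
    """Arithmetic mean contact distance per cell line."""
    out = {}
    for line, df in contacts_by_line.items():
        if not len(df):
            raise ContactError(f"no significant contacts for cell line {line}")
        out[line] = float(df["distance"].mean())
    return pd.Series(out, name="mean_distance")
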