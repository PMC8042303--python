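"""Cell-type-specific cRE calling from a normalized activity matrix.

Each cRE is tested once per cell type for *elevated* activity in that type
versus all remaining samples (one-vs-rest, one-sided). The test is a
moderated t on log2(RPM + 1): per-cRE residual variances from the one-way
cell-type layout are shrunk toward a common prior by empirical Bayes
(inverse-chi-square squeezing), which stabilises the 2-3-replicate design.
Per cell type, p-values are Benjamini-Hochberg adjusted across cREs; a cRE
is labeled with the cell type of its minimum q when that q clears alpha,
otherwise it is "constitutive".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

CONSTITUTIVE = "constitutive"


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-feature variances.

    Fits a scaled inverse-chi-square prior (prior df d0, location s2_0) to the
    observed residual variances by matching moments of log s2, then returns
    posterior variances (d0*s2_0 + df*s2) / (d0 + df) along with (d0, s2_0).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        # degenerate: nothing to moderate
        return s2.copy(), 0.0, float(np.nanmean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 1e-10:
        d0 = 2.0 * _trigamma_inverse(evar)
        s2_0 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s2_0 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s2_0 = np.exp(e.mean())
        post = np.full_like(s2, s2_0)
    return post, d0, s2_0


def one_vs_rest_test(activity: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """One-sided elevated-activity p-values per (cRE, cell type).

    activity: cRE x sample RPM matrix (not yet log scale).
    labels: sample -> cell type.
    Returns a cRE x cell-type DataFrame of p-values in (0, 1].
    """
    labels = pd.Series(labels).reindex(activity.columns)
    if labels.isna().any():
        raise ValueError(f"missing cell-type label for samples: {list(activity.columns[labels.isna()])}")
    types = list(pd.unique(labels))
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    X = np.log2(activity.to_numpy(dtype=float) + 1.0)
    n = X.shape[1]
    groups = {t: np.flatnonzero((labels == t).to_numpy()) for t in types}
    for t, idx in groups.items():
        if idx.size == 0:
            raise ValueError(f"cell type with zero samples: {t}")
    k = len(types)
    df_resid = n - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom (need n samples > n cell types)")
    # one-way residual variance per cRE
    rss = np.zeros(X.shape[0])
    gmeans = {}
    for t, idx in groups.items():
        sub = X[:, idx]
        m = sub.mean(axis=1)
        gmeans[t] = m
        rss += ((sub - m[:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid
    s2_post, d0, _ = squeeze_var(s2, df_resid)
    df_total = df_resid + (d0 if np.isfinite(d0) else 0.0)
    use_normal = not np.isfinite(d0)
    pmat = {}
    for t, idx in groups.items():
        rest = np.setdiff1d(np.arange(n), idx)
        diff = gmeans[t] - X[:, rest].mean(axis=1)
        se = np.sqrt(s2_post * (1.0 / idx.size + 1.0 / rest.size))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = diff / se
        if use_normal:
            p = stats.norm.sf(tstat)
        else:
            p = stats.t.sf(tstat, df_total)
        # degenerate zero-variance rows: no evidence either way
        p = np.where(se == 0, np.where(diff > 0, np.finfo(float).tiny, 1.0), p)
        pmat[t] = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(pmat, index=activity.index)


def fdr_by_type(pmat: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust each cell type's p-value column across cREs."""
    return pd.DataFrame(
        {t: bh_fdr(pmat[t].to_numpy()) for t in pmat.columns}, index=pmat.index
    )


def classify_specific(
    qmat: pd.DataFrame,
    activity: pd.DataFrame | None = None,
    labels: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign each cRE its cell type of minimum q, or "constitutive".

    Ties on the minimum q are broken toward the cell type with the larger
    mean activity (requires ``activity`` and ``labels``; without them, ties
    break on column order).
    """
    if qmat.isna().any().any():
        raise ValueError("q-value matrix must be complete")
    types = list(qmat.columns)
    q = qmat.to_numpy(dtype=float)
    if activity is not None and labels is not None:
        labels = pd.Series(labels).reindex(activity.columns)
        means = np.column_stack(
            [activity.loc[qmat.index, activity.columns[(labels == t).to_numpy()]].mean(axis=1) for t in types]
        )
    else:
        means = -np.arange(len(types))[None, :].repeat(len(qmat), axis=0)
    qmin = q.min(axis=1)
    # among argmin ties pick the largest mean activity
    is_min = q == qmin[:, None]
    masked = np.where(is_min, means, -np.inf)
    best = masked.argmax(axis=1)
    label = np.array(types, dtype=object)[best]
    specific = qmin < alpha
    calls = pd.DataFrame(
        {
            "cre_id": qmat.index,
            "cell_type": np.where(specific, label, CONSTITUTIVE),
            "fdr": qmin,
        }
    ).set_index("cre_id", drop=False)
    return calls


def z_transform_rows(matrix: pd.DataFrame, sd_mode: str = "population") -> pd.DataFrame:
    """Row-wise z-scores with population (n-denominator) standard deviation.

    Constant rows map to all-zero rows. A one-hot row over 6 columns yields
    the (-1/sqrt(5), ..., sqrt(5)) = (-0.447, ..., 2.236) pattern.
    """
    if sd_mode not in ("population", "sample"):
        raise ValueError("sd_mode must be 'population' or 'sample'")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    ddof = 0 if sd_mode == "population" else 1
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
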