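"""Distal cis-regulatory element (cRE) catalog construction.

A cRE catalog is built from per-sample H3K27ac peak calls in four steps:
keep peaks distal to promoters (> 2.5 kb from any TSS), merge peaks across
samples, stitch neighbouring merged peaks within 3 kb, and quantify activity
as quantile-normalized RPM over the stitched intervals.

Intervals are 0-based half-open ``[start, end)`` internally; coordinates
printed in reports are 1-based inclusive (``chrom:start+1-end``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


class CatalogError(ValueError):
    pass


def coord_1based(chrom: str, start: int, end: int) -> str:
    """Format a 0-based half-open interval as printed 1-based inclusive."""
    return f"{chrom}:{start + 1}-{end}"


def parse_coord_1based(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) to 0-based half-open."""
    chrom, _, span = text.partition(":")
    lo, _, hi = span.replace("‒", "-").replace("–", "-").partition("-")
    start1, end1 = int(lo), int(hi)
    if not chrom or start1 < 1 or end1 < start1:
        raise CatalogError(f"malformed coordinate string: {text!r}")
    return chrom, start1 - 1, end1


def _check_intervals(df: pd.DataFrame) -> pd.DataFrame:
    df = df[INTERVAL_COLS].copy()
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        raise CatalogError(f"{int(bad.sum())} invalid intervals (need 0 <= start < end)")
    return df


@dataclass
class CreCatalog:
    """Stitched distal intervals plus a per-sample activity matrix.

    cres: DataFrame with cre_id, chrom, start, end (sorted, disjoint).
    activity: DataFrame cre_id x sample_id of RPM values.
    sample_meta: DataFrame sample_id, cell_type.
    """

    cres: pd.DataFrame
    activity: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None
    normalized: bool = False
    _by_chrom: dict = field(default=None, repr=False, compare=False)

    def interval_index(self) -> dict:
        """chrom -> (starts, ends, cre_ids) arrays sorted by start."""
        if self._by_chrom is None:
            idx = {}
            for chrom, sub in self.cres.groupby("chrom", sort=False):
                sub = sub.sort_values("start")
                idx[chrom] = (
                    sub["start"].to_numpy(),
                    sub["end"].to_numpy(),
                    sub["cre_id"].to_numpy(),
                )
            self._by_chrom = idx
        return self._by_chrom


def filter_distal(peaks: pd.DataFrame, tss: pd.DataFrame, min_dist: int = 2500) -> pd.DataFrame:
    """Drop peaks within ``min_dist`` bp of any TSS.

    A peak ``[start, end)`` is removed iff some TSS position t satisfies
    ``start - min_dist <= t < end + min_dist``; equivalently the peak is kept
    only if every TSS is strictly farther than ``min_dist`` from the peak edge.
    """
    peaks = _check_intervals(peaks)
    if len(tss) == 0:
        warnings.warn("empty TSS list: no peaks filtered as promoter-proximal")
        return peaks.reset_index(drop=True)
    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in tss.groupby("chrom")}
    keep = np.ones(len(peaks), dtype=bool)
    for chrom, sub in peaks.groupby("chrom", sort=False):
        pos = tss_by_chrom.get(chrom)
        if pos is None:
            continue
        lo = sub["start"].to_numpy() - min_dist
        hi = sub["end"].to_numpy() + min_dist  # exclusive
        n_in = np.searchsorted(pos, hi, side="left") - np.searchsorted(pos, lo, side="left")
        keep[peaks.index.get_indexer(sub.index)] = n_in == 0
    return peaks[keep].reset_index(drop=True)


def merge_and_stitch(peak_sets: list[pd.DataFrame], stitch: int = 3000) -> pd.DataFrame:
    """Union all peak sets, then join intervals whose gap is <= ``stitch`` bp.

    Returns the catalog interval table (cre_id, chrom, start, end), sorted by
    (chrom, start), disjoint with all pairwise gaps > stitch.
    """
    frames = [_check_intervals(p) for p in peak_sets if len(p)]
    if not frames:
        return pd.DataFrame(columns=["cre_id", *INTERVAL_COLS])
    allp = pd.concat(frames, ignore_index=True).sort_values(["chrom", "start", "end"])
    out = []
    for chrom, sub in allp.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= stitch:  # overlap or stitchable gap
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    cat = pd.DataFrame(out, columns=INTERVAL_COLS)
    cat.insert(0, "cre_id", [f"cre_{i + 1:05d}" for i in range(len(cat))])
    return cat


def count_in_cres(catalog: CreCatalog | pd.DataFrame, sample_counts: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-sample per-interval fragment counts onto catalog cREs.

    ``sample_counts`` maps sample_id -> DataFrame(chrom, start, end, count).
    An input interval contributes its count to every cRE it overlaps by >= 1 bp.
    """
    cres = catalog.cres if isinstance(catalog, CreCatalog) else catalog
    cat = CreCatalog(cres) if not isinstance(catalog, CreCatalog) else catalog
    index = cat.interval_index()
    cre_ids = cres["cre_id"].to_numpy()
    mat = pd.DataFrame(0.0, index=pd.Index(cre_ids, name="cre_id"), columns=list(sample_counts))
    for sample, df in sample_counts.items():
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in index:
                continue
            starts, ends, ids = index[chrom]
            ps = sub["start"].to_numpy()
            pe = sub["end"].to_numpy()
            pc = sub["count"].to_numpy()
            # cREs with start < peak_end and end > peak_start
            first = np.searchsorted(ends, ps, side="right")
            last = np.searchsorted(starts, pe, side="left")
            for f, l, c in zip(first, last, pc):
                if l > f:
                    mat.loc[ids[f:l], sample] += c
    return mat


def quantify_rpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Reads-per-million: count / library_size * 1e6, per sample column."""
    libs = library_sizes.reindex(counts.columns)
    bad = libs.isna() | (libs <= 0)
    if bad.any():
        raise CatalogError(f"non-positive or missing library size for sample(s): {list(libs.index[bad])}")
    return counts / libs * 1e6


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean order-statistic reference.

    Each column is replaced by the across-column mean of sorted values at its
    ranks; tied values within a column receive the mean of the reference
    values at the tied positions. Afterwards every column has the identical
    sorted value multiset.
    """
    if matrix.isna().any().any():
        raise CatalogError("missing values not allowed in quantile normalization")
    if matrix.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        return matrix.copy()
    x = matrix.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col = np.empty(len(ref))
        col[order] = ref
        # ties share the mean of their reference values
        vals = x[order, j]
        i = 0
        while i < len(vals):
            k = i + 1
            while k < len(vals) and vals[k] == vals[i]:
                k += 1
            if k - i > 1:
                col[order[i:k]] = ref[i:k].mean()
            i = k
        out[:, j] = col
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def sample_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between sample columns over all cREs.

    Zero-variance columns yield NaN (undefined), never a silent 0.
    """
    if matrix.shape[0] < 2:
        raise CatalogError("need >= 2 cREs for sample correlation")
    return matrix.corr(method="pearson")
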