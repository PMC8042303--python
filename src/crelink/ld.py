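"""LD expansion of GWAS tag SNPs with cross-population recurrence.

Tag SNPs are expanded to proxy SNPs in tight LD (r^2 strictly > 0.8 by
default) when the association recurs in at least three of the available
population panels. Every expanded SNP carries its parental tag id, so the
expansion is fully traceable, and the tag itself is always a member of its
own expanded set. LD tables are treated as symmetric and deduplicated
keeping the maximum r^2 per (population, pair).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

_TAG_RE = re.compile(r"^(chr[\w]+)\.(\d+)$")

TAG_COLUMNS = ["tag_id", "rsid", "pvalue", "trait", "source"]
LD_COLUMNS = ["population", "snp_a", "snp_b", "r2"]


class LdError(ValueError):
    pass


def parse_locus(snp_id: str) -> tuple[str, int]:
    """Parse a ``chrN.position`` SNP/tag id into (chrom, 1-based position)."""
    m = _TAG_RE.match(str(snp_id))
    if not m or int(m.group(2)) <= 0:
        raise LdError(f"malformed SNP/tag id: {snp_id!r} (expected 'chrN.position')")
    return m.group(1), int(m.group(2))


def _tidy_ld(ld: pd.DataFrame) -> pd.DataFrame:
    """Symmetrize and deduplicate LD rows, keeping max r2 per (pop, pair)."""
    ld = ld[LD_COLUMNS].copy()
    r2 = ld["r2"].to_numpy(dtype=float)
    if np.any((r2 < 0) | (r2 > 1) | ~np.isfinite(r2)):
        raise LdError("r2 values must lie in [0, 1]")
    a = ld["snp_a"].astype(str)
    b = ld["snp_b"].astype(str)
    lo = np.where(a <= b, a, b)
    hi = np.where(a <= b, b, a)
    tidy = pd.DataFrame({"population": ld["population"].astype(str), "lo": lo, "hi": hi, "r2": r2})
    return tidy.groupby(["population", "lo", "hi"], as_index=False)["r2"].max()


def expand_tags(
    tags: pd.DataFrame,
    ld: pd.DataFrame,
    r2_min: float = 0.8,
    min_pops: int = 3,
) -> pd.DataFrame:
    """Expand each tag SNP into its LD proxy set.

    tags: DataFrame with at least ``tag_id`` (chrN.position) columns.
    ld: long DataFrame (population, snp_a, snp_b, r2) over all populations.
    Returns one row per (parent tag, locus): the tag itself plus every SNP
    with r2 > r2_min with that tag in >= min_pops populations. Columns:
    parent_tag, snp_id, chrom, pos, n_supporting_populations, r2_by_population.
    """
    n_pops_avail = ld["population"].nunique() if len(ld) else 0
    if len(ld) and n_pops_avail < min_pops:
        raise LdError(f"only {n_pops_avail} population panels available; need >= {min_pops}")
    tidy = _tidy_ld(ld) if len(ld) else pd.DataFrame(columns=["population", "lo", "hi", "r2"])
    records = []
    for tag in tags["tag_id"].astype(str):
        chrom, pos = parse_locus(tag)
        records.append(
            {
                "parent_tag": tag,
                "snp_id": tag,
                "chrom": chrom,
                "pos": pos,
                "n_supporting_populations": n_pops_avail,
                "r2_by_population": {},
                "is_tag": True,
            }
        )
        sub = tidy[(tidy["lo"] == tag) | (tidy["hi"] == tag)]
        if not len(sub):
            continue
        partner = np.where(sub["lo"] == tag, sub["hi"], sub["lo"])
        sub = sub.assign(partner=partner)
        strong = sub[sub["r2"].to_numpy() > r2_min]
        for snp, grp in strong.groupby("partner", sort=True):
            if grp["population"].nunique() >= min_pops:
                c, p = parse_locus(snp)
                records.append(
                    {
                        "parent_tag": tag,
                        "snp_id": snp,
                        "chrom": c,
                        "pos": p,
                        "n_supporting_populations": int(grp["population"].nunique()),
                        "r2_by_population": dict(zip(grp["population"], grp["r2"])),
                        "is_tag": False,
                    }
                )
    return pd.DataFrame(
        records,
        columns=[
            "parent_tag",
            "snp_id",
            "chrom",
            "pos",
            "n_supporting_populations",
            "r2_by_population",
            "is_tag",
        ],
    )


def expansion_summary(expanded: pd.DataFrame) -> dict:
    """Counts over an expanded SNP table (unique loci)."""
    n_tags = expanded["parent_tag"].nunique() if len(expanded) else 0
    n_loci = expanded["snp_id"].nunique() if len(expanded) else 0
    proxies = expanded[~expanded["is_tag"]] if len(expanded) else expanded
    mean_proxies = len(proxies) / n_tags if n_tags else 0.0
    return {
        "n_tags": int(n_tags),
        "n_expanded_snps": int(n_loci),
        "mean_proxies_per_tag": float(mean_proxies),
    }
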