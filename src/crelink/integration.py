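"""SNP-cRE overlap, tag-level rollup, target-gene inference and reports.

Connects the upstream layers: LD-expanded SNPs are intersected with the cRE
catalog (1-based inclusive containment), linked tags are rolled up into
specific / constitutive-only classes, and SNP-harboring cell-type-specific
cREs are joined to gene promoters through the union set of promoter-anchored
chromatin interactions. The emitted tables mirror the annotated-SNP and
inferred-target-gene report layouts.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CreCatalog, coord_1based, parse_coord_1based
from .specificity import CONSTITUTIVE

TABLE1_COLUMNS = ["tag_snp", "rsid", "snp_p", "trait", "cre", "fdr", "cell_type"]


def percentage(numerator: int, denominator: int) -> float:
    """100 * n / d, rounded half-up to two decimals (report convention)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def overlap_snps_cres(
    expanded: pd.DataFrame, catalog: CreCatalog, calls: pd.DataFrame
) -> pd.DataFrame:
    """One association per (expanded SNP, containing cRE).

    SNP positions are 1-based; containment is inclusive on both ends of the
    printed 1-based cRE interval, i.e. start < pos <= end on the internal
    0-based half-open interval.
    """
    index = catalog.interval_index()
    calls = calls.set_index("cre_id") if calls.index.name != "cre_id" else calls
    rows = []
    for rec in expanded.itertuples(index=False):
        idx = index.get(rec.chrom)
        if idx is None:
            continue
        starts, ends, ids = idx
        i = int(np.searchsorted(starts, rec.pos, side="left")) - 1
        if i >= 0 and rec.pos <= ends[i]:
            cre_id = ids[i]
            rows.append(
                {
                    "tag_id": rec.parent_tag,
                    "snp_id": rec.snp_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "cre_id": cre_id,
                    "cre_start": int(starts[i]),
                    "cre_end": int(ends[i]),
                    "cell_type": calls.loc[cre_id, "cell_type"],
                    "fdr": float(calls.loc[cre_id, "fdr"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["tag_id", "snp_id", "chrom", "pos", "cre_id", "cre_start", "cre_end", "cell_type", "fdr"],
    )


def tag_rollup(associations: pd.DataFrame, tags: pd.DataFrame) -> dict:
    """Tag-level linkage counts and percentages.

    A tag is linked iff any of its expanded SNPs (itself included) falls in a
    cRE; linked tags split into specific-linked (>= 1 association with a
    cell-type-specific cRE) and constitutive-only. Duplicate (tag, SNP, cRE)
    records are deduplicated first.
    """
    n_tags = tags["tag_id"].nunique()
    if n_tags == 0:
        raise ValueError("zero tags")
    assoc = associations.drop_duplicates(["tag_id", "snp_id", "cre_id"])
    linked = set(assoc["tag_id"])
    specific = set(assoc.loc[assoc["cell_type"] != CONSTITUTIVE, "tag_id"])
    return {
        "n_tags": int(n_tags),
        "n_linked": len(linked),
        "n_specific_linked": len(specific),
        "n_constitutive_only": len(linked - specific),
        "pct_linked": percentage(len(linked), n_tags),
        "pct_specific_linked": percentage(len(specific), n_tags),
    }


def infer_targets(
    associations: pd.DataFrame,
    union: pd.DataFrame,
    resolution: int = 5000,
) -> pd.DataFrame:
    """Target genes of SNP-harboring cell-type-specific cREs.

    For each specific-cRE association, every union-set promoter interaction
    whose distal 5 kb bin overlaps the cRE interval by >= 1 bp yields a
    TargetAssignment carrying the cRE's cell type, supporting cell lines and
    bin distance.
    """
    spec = associations[associations["cell_type"] != CONSTITUTIVE]
    cres = spec.drop_duplicates("cre_id")
    by_bin: dict[tuple, list] = {}
    for rec in union.itertuples(index=False):
        by_bin.setdefault((rec.chrom, int(rec.distal_bin)), []).append(rec)
    rows = []
    for cre in cres.itertuples(index=False):
        b_lo = cre.cre_start // resolution
        b_hi = (cre.cre_end - 1) // resolution
        hits = {}
        for b in range(b_lo, b_hi + 1):
            for rec in by_bin.get((cre.chrom, b), ()):
                hits.setdefault(rec.gene_id, rec)
        tags_of_cre = spec.loc[spec["cre_id"] == cre.cre_id, "tag_id"].unique()
        for gene, rec in sorted(hits.items()):
            for tag in tags_of_cre:
                rows.append(
                    {
                        "tag_id": tag,
                        "cre_id": cre.cre_id,
                        "chrom": cre.chrom,
                        "cre_start": cre.cre_start,
                        "cre_end": cre.cre_end,
                        "cell_type": cre.cell_type,
                        "fdr": cre.fdr,
                        "gene_id": gene,
                        "support": rec.support,
                        "n_support": int(rec.n_support),
                        "distance": int(rec.distance),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "tag_id", "cre_id", "chrom", "cre_start", "cre_end", "cell_type",
            "fdr", "gene_id", "support", "n_support", "distance",
        ],
    )


# ---------------------------------------------------------------------------
# report building


def _order_by_type_count(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic report ordering: cell types by descending row count,
    then cell type name, then locus, then tag."""
    counts = df["cell_type"].value_counts()
    df = df.assign(
        _n=-df["cell_type"].map(counts),
        _chrom=df["cre"].map(lambda c: parse_coord_1based(c)[0]),
        _start=df["cre"].map(lambda c: parse_coord_1based(c)[1]),
    )
    df = df.sort_values(["_n", "cell_type", "_chrom", "_start", "tag_snp"], kind="stable")
    return df.drop(columns=["_n", "_chrom", "_start"]).reset_index(drop=True)


def format_table1(rows: pd.DataFrame) -> pd.DataFrame:
    """Canonical annotated-tag-SNP table (one row per tag x specific cRE)."""
    df = rows[TABLE1_COLUMNS].drop_duplicates(["tag_snp", "cre"]).copy()
    df["snp_p"] = df["snp_p"].map(lambda v: f"{float(v):.2e}")
    df["fdr"] = df["fdr"].map(lambda v: f"{float(v):.2e}")
    return _order_by_type_count(df)


def build_table1(associations: pd.DataFrame, tags: pd.DataFrame) -> pd.DataFrame:
    spec = associations[associations["cell_type"] != CONSTITUTIVE]
    if not len(spec):
        return pd.DataFrame(columns=TABLE1_COLUMNS)
    merged = spec.merge(
        tags.rename(columns={"tag_id": "tag_snp"}), left_on="tag_id", right_on="tag_snp"
    )
    merged["cre"] = [
        coord_1based(c, s, e) for c, s, e in zip(merged["chrom"], merged["cre_start"], merged["cre_end"])
    ]
    merged = merged.rename(columns={"pvalue": "snp_p"})
    return format_table1(merged)


def build_table2(targets: pd.DataFrame, tags: pd.DataFrame, z: pd.DataFrame) -> pd.DataFrame:
    """Inferred-target-gene table with per-cell-type z-scored expression."""
    zcols = list(z.columns)
    cols = ["gene_id", "cre", "cell_type", "fdr", "tag_snp", "rsid", "snp_p", "trait"] + zcols
    if not len(targets):
        return pd.DataFrame(columns=cols)
    df = targets.merge(tags.rename(columns={"tag_id": "tag_snp"}), left_on="tag_id", right_on="tag_snp")
    df = df[df["gene_id"].isin(z.index)]
    df["cre"] = [
        coord_1based(c, s, e) for c, s, e in zip(df["chrom"], df["cre_start"], df["cre_end"])
    ]
    df = df.rename(columns={"pvalue": "snp_p"})
    for c in zcols:
        df[c] = z.loc[df["gene_id"], c].to_numpy().round(3)
    df["snp_p"] = df["snp_p"].map(lambda v: f"{float(v):.2e}")
    df["fdr"] = df["fdr"].map(lambda v: f"{float(v):.2e}")
    counts = df["cell_type"].value_counts()
    zown = np.array([df.loc[i, t] if (t := df.loc[i, "cell_type"]) in zcols else np.nan for i in df.index])
    df = (
        df.assign(_n=-df["cell_type"].map(counts), _z=-zown)
        .sort_values(["_n", "cell_type", "_z", "gene_id"], kind="stable")
        .drop(columns=["_n", "_z"])
        .reset_index(drop=True)
    )
    return df[cols]


def build_report(
    associations: pd.DataFrame,
    targets: pd.DataFrame,
    tags: pd.DataFrame,
    z: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> dict:
    """Assemble the two report tables plus a JSON summary; optionally write them."""
    table1 = build_table1(associations, tags)
    table2 = build_table2(targets, tags, z)
    summary = tag_rollup(associations, tags) if len(tags) else {}
    summary.update(
        n_target_assignments=int(len(targets)),
        n_target_genes=int(targets["gene_id"].nunique()) if len(targets) else 0,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)
        table2.to_csv(out / "table2.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        snp_cres = associations.drop_duplicates("cre_id")
        bed = snp_cres[["chrom", "cre_start", "cre_end", "cre_id"]]
        bed.to_csv(out / "snp_harboring_cres.bed", sep="\t", index=False, header=False)
    return {"table1": table1, "table2": table2, "summary": summary}


# ---------------------------------------------------------------------------
# packaged reference tables


def _data_path(name: str):
    return resources.files("crelink.data").joinpath(name)


def load_table1_fixture() -> pd.DataFrame:
    """Parse the packaged annotated-tag-SNP reference table.

    Returns typed columns: snp_p and fdr as floats and the cRE interval also
    split into chrom / start / end (0-based half-open).
    """
    with resources.as_file(_data_path("table1.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    df["snp_p"] = df["snp_p"].astype(float)
    df["fdr"] = df["fdr"].astype(float)
    parsed = df["cre"].map(parse_coord_1based)
    df["chrom"] = parsed.map(lambda t: t[0])
    df["start"] = parsed.map(lambda t: t[1])
    df["end"] = parsed.map(lambda t: t[2])
    return df


def load_table2_fixture() -> pd.DataFrame:
    """Parse the packaged inferred-target-gene reference table."""
    with resources.as_file(_data_path("table2.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    for c in df.columns[9:]:
        df[c] = df[c].astype(float)
    return df


def load_marker_genes() -> pd.DataFrame:
    """Reference marker genes used to label lung cell populations."""
    with resources.as_file(_data_path("marker_genes.tsv")) as path:
        return pd.read_csv(path, sep="\t")
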