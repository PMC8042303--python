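"""Synthetic study generator with planted ground truth.

Emits every input the annotation pipeline consumes — per-sample H3K27ac peak
calls with fragment counts, a tag-SNP catalog with per-population LD tables,
sparse 5 kb contact matrices per cell line, and a cell-labeled single-cell
count matrix — over a small synthetic genome, together with a GroundTruth
record of everything that was planted:

* a fraction of cREs is elevated ``specific_fold``-times in exactly one cell
  type (negative-binomial count noise, dispersion 0.1);
* tag SNPs carry proxy SNPs in tight LD recurrent in >= 3 of 5 population
  panels; decoy proxies recur in exactly 2 panels and must be rejected;
* contact counts follow a d^-decay_exponent background (Poisson), with
  planted promoter-cRE loops multiplied by ``loop_fold`` at 30-250 kb;
* single-cell counts are cell-type structured with planted one-type genes
  at ``expr_fold`` and deliberately planted QC-violating cells.

A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.io import mmwrite

from .contacts import ContactMatrix

CELL_TYPES = (
    "Myeloid", "Bcell", "Tcell", "NK", "Epithelial", "Fibroblast", "Endothelial", "Cancer",
)
CELL_LINES = ("CL_A", "CL_B", "CL_C", "CL_D")
TRAITS = (
    "Familial lung adenocarcinoma",
    "Familial lung cancer",
    "Familial squamous cell lung carcinoma",
    "Non-small cell lung cancer",
    "Non-small cell lung cancer (recurrence rate)",
    "Non-small cell lung cancer (survival)",
    "Small cell lung cancer (survival)",
    "Small cell lung carcinoma",
    "Squamous cell lung carcinoma",
)


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    n_cell_types: int = 8
    samples_per_type: int = 3
    genome: tuple = (("chrS1", 8_000_000), ("chrS2", 8_000_000))
    n_cres: int = 300
    frac_specific: float = 0.4
    specific_fold: float = 8.0
    n_tags: int = 30
    n_populations: int = 5
    ld_r2_high: float = 0.9
    loop_fold: float = 10.0
    decay_exponent: float = 1.0
    n_cells_per_type: int = 60
    frac_mito: float = 0.05
    expr_fold: float = 8.0
    # secondary scales (documented in docs/methods.md)
    gene_spacing: int = 20_000
    peak_base_mean: float = 50.0
    nb_dispersion: float = 0.1
    hic_base: float = 200.0
    resolution: int = 5000
    loop_dist_range: tuple = (30_000, 250_000)
    sc_base_mean: float = 1.0
    frac_qc_bad: float = 0.05

    def validate(self) -> None:
        if self.n_cell_types < 2 or self.n_cell_types > len(CELL_TYPES):
            raise SimConfigError(f"n_cell_types must be in [2, {len(CELL_TYPES)}]")
        for chrom, length in self.genome:
            if length <= 0 or not chrom:
                raise SimConfigError(f"invalid genome entry: {(chrom, length)}")
        for name in ("frac_specific", "frac_mito", "frac_qc_bad"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SimConfigError(f"{name} must lie in [0, 1)")
        if self.n_populations < 1:
            raise SimConfigError("n_populations must be >= 1")
        if not 0 < self.ld_r2_high <= 1:
            raise SimConfigError("ld_r2_high must lie in (0, 1]")
        if self.decay_exponent <= 0:
            raise SimConfigError("decay_exponent must be positive")
        if self.specific_fold < 1 or self.loop_fold < 1 or self.expr_fold < 1:
            raise SimConfigError("fold changes must be >= 1")
        if self.n_cells_per_type < 10:
            raise SimConfigError("n_cells_per_type must be >= 10")
        lo, hi = self.loop_dist_range
        max_len = max(length for _, length in self.genome)
        if lo < 6 * self.resolution or hi > min(1_000_000, max_len):
            raise SimConfigError("loop distances must lie within [30 kb, min(1 Mb, chrom length)]")

    @property
    def cell_types(self) -> tuple:
        return CELL_TYPES[: self.n_cell_types]

    @property
    def populations(self) -> tuple:
        return tuple(f"POP{i + 1}" for i in range(self.n_populations))


@dataclass
class GroundTruth:
    """Planted structure, keyed by the ids used in the generated files."""

    specific_cres: dict = field(default_factory=dict)  # cell_type -> [planted cre ids]
    cre_intervals: pd.DataFrame | None = None  # planted_id, chrom, start, end, label
    tag_map: dict = field(default_factory=dict)  # tag -> {"proxies": [...], "decoys": [...]}
    snp_cres: dict = field(default_factory=dict)  # planted cre id -> {tag, snps, cell_type}
    tag_classes: dict = field(default_factory=dict)  # tag -> specific|constitutive|unlinked
    loops: list = field(default_factory=list)  # {cre, gene, chrom, bins, cell_lines, distance}
    elevated_genes: dict = field(default_factory=dict)  # cell_type -> [gene ids]
    qc_cells: dict = field(default_factory=dict)  # {"low_genes": [...], "high_mito": [...]}

    def to_json(self) -> str:
        d = {
            "specific_cres": self.specific_cres,
            "cre_intervals": self.cre_intervals.to_dict(orient="records"),
            "tag_map": self.tag_map,
            "snp_cres": self.snp_cres,
            "tag_classes": self.tag_classes,
            "loops": self.loops,
            "elevated_genes": self.elevated_genes,
            "qc_cells": self.qc_cells,
        }
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SimResult:
    config: SimConfig
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, mito
    peaks: dict  # sample_id -> DataFrame(chrom, start, end, count)
    library_sizes: pd.Series
    sample_meta: pd.DataFrame  # sample_id, cell_type
    tags: pd.DataFrame  # tag_id, rsid, pvalue, trait, source
    ld: pd.DataFrame  # population, snp_a, snp_b, r2
    contact_matrices: dict  # (cell_line, chrom) -> ContactMatrix
    adata: AnnData
    truth: GroundTruth


def _nb(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative binomial (Poisson-gamma) with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# gene / cRE layout


def gen_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for chrom, length in config.genome:
        pos = 10_000
        while pos + 300_000 < length:
            tss = int(pos + rng.integers(0, 5_001))
            rows.append((f"G{i + 1:04d}", chrom, tss, "+"))
            pos += config.gene_spacing
            i += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    n_mito = int(round(config.frac_mito * len(genes)))
    mito_idx = rng.choice(len(genes), size=n_mito, replace=False)
    genes["mito"] = False
    genes.loc[mito_idx, "mito"] = True
    genes.loc[genes["mito"], "gene_id"] = [
        f"MT-{g}" for g in genes.loc[genes["mito"], "gene_id"]
    ]
    return genes


def gen_peaks(config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator):
    """Per-sample peak calls + counts, with planted cell-type-specific cREs.

    Every sample carries a (jittered) peak at every planted cRE; specific
    cREs get ``specific_fold`` higher mean counts in their own cell type.
    Promoter-proximal decoy peaks are added to exercise the distal filter.
    """
    config.validate()
    n_spec = int(round(config.n_cres * config.frac_specific))
    nuclear = genes[~genes["mito"]].reset_index(drop=True)
    slots = rng.choice(len(nuclear), size=config.n_cres, replace=False)
    slots.sort()
    cre_rows = []
    for j, slot in enumerate(slots):
        g = nuclear.iloc[slot]
        start = int(g["tss"] + rng.integers(4_000, 8_001))
        width = int(rng.integers(1_000, 2_001))
        cre_rows.append((f"pcre_{j + 1:04d}", g["chrom"], start, start + width))
    order = rng.permutation(config.n_cres)
    labels = np.array(["shared"] * config.n_cres, dtype=object)
    types = config.cell_types
    for rank, idx in enumerate(order[:n_spec]):
        labels[idx] = types[rank % len(types)]
    cre_df = pd.DataFrame(cre_rows, columns=["planted_id", "chrom", "start", "end"])
    cre_df["label"] = labels

    # promoter-proximal decoys (should be removed by the distal filter)
    n_decoy = max(5, config.n_cres // 10)
    decoy_slots = rng.choice(
        np.setdiff1d(np.arange(len(nuclear)), slots), size=n_decoy, replace=False
    )
    decoys = [
        (nuclear.iloc[s]["chrom"], int(nuclear.iloc[s]["tss"] - 500), int(nuclear.iloc[s]["tss"] + 500))
        for s in sorted(decoy_slots)
    ]

    sample_meta = []
    peaks = {}
    lib = {}
    for t in types:
        for r in range(config.samples_per_type):
            sid = f"{t}_{r + 1}"
            sample_meta.append((sid, t))
            means = np.where(
                labels == t, config.peak_base_mean * config.specific_fold, config.peak_base_mean
            )
            counts = _nb(rng, means, config.nb_dispersion)
            jit = rng.integers(-200, 201, size=(config.n_cres, 2))
            df = pd.DataFrame(
                {
                    "chrom": cre_df["chrom"],
                    "start": np.maximum(cre_df["start"].to_numpy() + jit[:, 0], 0),
                    "end": cre_df["end"].to_numpy() + jit[:, 1],
                    "count": counts,
                }
            )
            dcounts = _nb(rng, np.full(n_decoy, config.peak_base_mean), config.nb_dispersion)
            ddf = pd.DataFrame(decoys, columns=["chrom", "start", "end"])
            ddf["count"] = dcounts
            peaks[sid] = (
                pd.concat([df, ddf], ignore_index=True)
                .sort_values(["chrom", "start"])
                .reset_index(drop=True)
            )
            lib[sid] = int(rng.integers(1_800_000, 2_200_001))
    truth_part = {
        "cre_intervals": cre_df,
        "specific_cres": {
            t: cre_df.loc[cre_df["label"] == t, "planted_id"].tolist() for t in types
        },
    }
    return peaks, pd.Series(lib, name="library_size"), pd.DataFrame(sample_meta, columns=["sample_id", "cell_type"]), truth_part


# ---------------------------------------------------------------------------
# tag SNPs and LD


def gen_ld(config: SimConfig, genes: pd.DataFrame, cre_df: pd.DataFrame, rng: np.random.Generator):
    """Tag catalog + per-population LD tables with planted and decoy proxies."""
    config.validate()
    if config.n_populations < 3:
        raise SimConfigError("LD recurrence rule needs n_populations >= 3")
    types = config.cell_types
    spec_cres = cre_df[cre_df["label"] != "shared"].reset_index(drop=True)
    const_cres = cre_df[cre_df["label"] == "shared"].reset_index(drop=True)
    n_spec_tags = min(12, config.n_tags // 3, len(spec_cres))
    n_const_tags = min(6, config.n_tags // 5, len(const_cres))

    nuclear = genes[~genes["mito"]].reset_index(drop=True)
    tss_sorted = {c: g.sort_values("tss") for c, g in nuclear.groupby("chrom")}
    used_genes: set = set()  # genes whose promoter region already hosts a tag

    def host_gene(cre):
        """The gene whose TSS sits immediately upstream of a planted cRE."""
        g = tss_sorted[cre["chrom"]]
        i = int(g["tss"].searchsorted(cre["start"])) - 1
        return g.iloc[i]

    tags = []
    ld_rows = []  # population, snp_a, snp_b, r2
    tag_map = {}
    snp_cres = {}
    tag_classes = {}
    pops = config.populations
    used_cres = set()
    rsid_counter = 900_000

    spec_pool = spec_cres.sample(frac=1.0, random_state=int(rng.integers(2**31)))

    def add_tag(chrom, pos):
        nonlocal rsid_counter
        rsid_counter += 1
        tag_id = f"{chrom}.{pos}"
        tags.append(
            {
                "tag_id": tag_id,
                "rsid": f"rs{rsid_counter}",
                "pvalue": float(10 ** -rng.uniform(6, 16)),
                "trait": TRAITS[len(tags) % len(TRAITS)],
                "source": "synthetic",
            }
        )
        tag_map[tag_id] = {"proxies": [], "decoys": []}
        return tag_id

    def add_proxy(tag_id, chrom, pos, n_sup):
        snp_id = f"{chrom}.{pos}"
        chosen = rng.choice(len(pops), size=n_sup, replace=False)
        for pi in range(len(pops)):
            r2 = config.ld_r2_high if pi in chosen else float(rng.uniform(0.1, 0.5))
            a, b = (tag_id, snp_id) if rng.random() < 0.5 else (snp_id, tag_id)
            ld_rows.append((pops[pi], a, b, r2))
        return snp_id

    def add_decoy(tag_id, chrom, pos):
        snp_id = f"{chrom}.{pos}"
        chosen = rng.choice(len(pops), size=2, replace=False)
        for pi in chosen:
            ld_rows.append((pops[pi], tag_id, snp_id, 0.95))
        return snp_id

    def plant_linked(cre_rows, n_tags_here, klass):
        picked = cre_rows.iloc[:n_tags_here]
        for _, cre in picked.iterrows():
            host = host_gene(cre)
            used_genes.add(host["gene_id"])
            tag_id = add_tag(cre["chrom"], int(host["tss"]) - 5_000)
            tag_classes[tag_id] = klass
            n_prox = int(rng.integers(1, 3))
            snps = []
            for _ in range(n_prox):
                pos = int(rng.integers(cre["start"] + 1, cre["end"] + 1))
                n_sup = int(rng.integers(3, config.n_populations + 1))
                snps.append(add_proxy(tag_id, cre["chrom"], pos, n_sup))
            tag_map[tag_id]["proxies"] = sorted(set(snps))
            snp_cres[cre["planted_id"]] = {
                "tag": tag_id,
                "snps": sorted(set(snps)),
                "cell_type": cre["label"],
            }
            used_cres.add(cre["planted_id"])

    plant_linked(spec_pool, n_spec_tags, "specific")
    const_pool = const_cres.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    plant_linked(const_pool, n_const_tags, "constitutive")

    # unlinked tags: proxies (if any) fall outside every cRE
    n_unlinked = config.n_tags - n_spec_tags - n_const_tags
    free = nuclear[~nuclear["gene_id"].isin(used_genes)].sample(
        n=n_unlinked, random_state=int(rng.integers(2**31))
    )
    for _, g in free.iterrows():
        tag_id = add_tag(g["chrom"], int(g["tss"]) - 5_000)
        tag_classes[tag_id] = "unlinked"
        if rng.random() < 0.5:
            pos = int(g["tss"]) - 3_000  # between promoter and the distal zone
            n_sup = int(rng.integers(3, config.n_populations + 1))
            tag_map[tag_id]["proxies"] = [add_proxy(tag_id, g["chrom"], pos, n_sup)]

    # decoy proxies: r2 high in exactly 2 populations, inside unused cREs
    unused = cre_df[~cre_df["planted_id"].isin(used_cres)].reset_index(drop=True)
    tag_ids = [t["tag_id"] for t in tags]
    n_decoy = min(8, len(unused), len(tag_ids))
    for di in range(n_decoy):
        cre = unused.iloc[di]
        tag_id = tag_ids[int(rng.integers(0, len(tag_ids)))]
        pos = int(rng.integers(cre["start"] + 1, cre["end"] + 1))
        tag_map[tag_id]["decoys"].append(add_decoy(tag_id, cre["chrom"], pos))

    # background noise pairs, weak LD in every population
    for _ in range(50):
        g = nuclear.iloc[int(rng.integers(0, len(nuclear)))]
        a = f"{g['chrom']}.{int(g['tss']) - 2_000}"
        b = f"{g['chrom']}.{int(g['tss']) - 1_000}"
        for pop in pops:
            ld_rows.append((pop, a, b, float(rng.uniform(0.05, 0.4))))

    tags_df = pd.DataFrame(tags)
    ld_df = pd.DataFrame(ld_rows, columns=["population", "snp_a", "snp_b", "r2"])
    truth_part = {"tag_map": tag_map, "snp_cres": snp_cres, "tag_classes": tag_classes}
    return tags_df, ld_df, truth_part


# ---------------------------------------------------------------------------
# contact matrices


def gen_contacts(config: SimConfig, genes: pd.DataFrame, snp_cres: dict, cre_df: pd.DataFrame,
                 rng: np.random.Generator):
    """Per-cell-line sparse contact maps with planted promoter-cRE loops.

    Background pair counts at bin distance k are Poisson with mean
    ``hic_base * k^-decay_exponent``; planted loops multiply that mean by
    ``loop_fold`` and join a SNP-harboring specific cRE's bin to a TSS bin
    30-250 kb away (always intra-chromosomal, within the tested window).
    """
    config.validate()
    res = config.resolution
    chrom_len = dict(config.genome)
    cre_lookup = cre_df.set_index("planted_id")
    lo_d, hi_d = config.loop_dist_range

    loops = []
    elevated_seed = {}
    used_targets: set = set()
    nuclear = genes[~genes["mito"]]
    for planted_id, info in sorted(snp_cres.items()):
        if info["cell_type"] == "shared":
            continue
        cre = cre_lookup.loc[planted_id]
        cre_bin = int((cre["start"] + cre["end"]) // 2 // res)
        cand = nuclear[nuclear["chrom"] == cre["chrom"]].copy()
        cand["tss_bin"] = cand["tss"] // res
        d = (cand["tss_bin"] - cre_bin).abs() * res
        cand = cand[(d >= lo_d) & (d <= hi_d) & ~cand["gene_id"].isin(used_targets)]
        if not len(cand):
            continue
        target = cand.iloc[int(rng.integers(0, len(cand)))]
        used_targets.add(target["gene_id"])
        lines = sorted(rng.choice(CELL_LINES, size=2, replace=False).tolist())
        loops.append(
            {
                "cre": planted_id,
                "gene": target["gene_id"],
                "chrom": cre["chrom"],
                "cre_bin": cre_bin,
                "tss_bin": int(target["tss_bin"]),
                "cell_lines": lines,
                "distance": int(abs(int(target["tss_bin"]) - cre_bin) * res),
                "cell_type": info["cell_type"],
                "tag": info["tag"],
            }
        )
        elevated_seed.setdefault(info["cell_type"], []).append(target["gene_id"])

    matrices = {}
    kmax_window = 1_000_000 // res
    for line in CELL_LINES:
        for chrom, length in config.genome:
            n_bins = length // res
            rows_i, rows_j, rows_c = [], [], []
            for k in range(1, min(kmax_window + 20, n_bins)):
                mu = config.hic_base * k ** (-config.decay_exponent)
                counts = rng.poisson(mu, n_bins - k)
                nz = np.flatnonzero(counts)
                rows_i.append(nz)
                rows_j.append(nz + k)
                rows_c.append(counts[nz])
            counts_by_pair = dict(
                zip(
                    zip(np.concatenate(rows_i).tolist(), np.concatenate(rows_j).tolist()),
                    np.concatenate(rows_c).tolist(),
                )
            )
            for loop in loops:
                if loop["chrom"] != chrom or line not in loop["cell_lines"]:
                    continue
                bi, bj = sorted((loop["cre_bin"], loop["tss_bin"]))
                k = bj - bi
                mu = config.hic_base * k ** (-config.decay_exponent)
                extra = int(rng.poisson(mu * (config.loop_fold - 1.0)))
                if extra > 0:
                    counts_by_pair[(bi, bj)] = counts_by_pair.get((bi, bj), 0) + extra
            pairs = sorted(counts_by_pair)
            tri = pd.DataFrame(
                {
                    "bin_i": [p[0] for p in pairs],
                    "bin_j": [p[1] for p in pairs],
                    "count": [counts_by_pair[p] for p in pairs],
                }
            )
            matrices[(line, chrom)] = ContactMatrix(
                cell_line=line, chrom=chrom, chrom_length=length, triplets=tri, resolution=res
            )
    return matrices, {"loops": loops, "elevated_seed": elevated_seed}


# ---------------------------------------------------------------------------
# single-cell matrix


def gen_scrna(config: SimConfig, genes: pd.DataFrame, elevated_seed: dict, rng: np.random.Generator):
    """Cell-type-structured single-cell counts with planted markers and QC traps."""
    config.validate()
    if config.frac_mito >= 1:
        raise SimConfigError("frac_mito must be < 1")
    types = config.cell_types
    n_genes = len(genes)
    gene_ids = genes["gene_id"].to_numpy()
    mito = genes["mito"].to_numpy()
    base = rng.lognormal(mean=np.log(config.sc_base_mean), sigma=1.0, size=n_genes)

    # planted one-type genes: loop targets plus extra markers per type
    elevated = {t: list(elevated_seed.get(t, [])) for t in types}
    taken = {g for gs in elevated.values() for g in gs}
    free = [g for g, m in zip(gene_ids, mito) if not m and g not in taken]
    free_idx = rng.permutation(len(free))
    ptr = 0
    for t in types:
        extra = [free[i] for i in free_idx[ptr : ptr + 8]]
        ptr += 8
        elevated[t].extend(extra)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    fold = np.ones((len(types), n_genes))
    for ti, t in enumerate(types):
        for g in elevated[t]:
            fold[ti, gene_pos[g]] = config.expr_fold

    rows = []
    labels = []
    for ti, t in enumerate(types):
        mean = base * fold[ti]
        counts = _nb(rng, np.tile(mean, (config.n_cells_per_type, 1)), config.nb_dispersion)
        rows.append(counts)
        labels.extend([t] * config.n_cells_per_type)
    X = np.vstack(rows)
    cell_ids = [f"cell_{i + 1:04d}" for i in range(X.shape[0])]

    # deliberately planted QC violators: first cells of each type
    n_bad = max(1, int(round(config.frac_qc_bad * config.n_cells_per_type)))
    low_gene_cells, high_mito_cells = [], []
    mito_idx = np.flatnonzero(mito)
    for ti in range(len(types)):
        offs = ti * config.n_cells_per_type
        for b in range(n_bad):
            ci = offs + b
            row = np.zeros(n_genes, dtype=X.dtype)
            nonmito = np.flatnonzero(~mito)
            keep = rng.choice(nonmito, size=min(150, len(nonmito)), replace=False)
            row[keep] = 1
            X[ci] = row
            low_gene_cells.append(cell_ids[ci])
        if len(mito_idx):
            for b in range(n_bad):
                ci = offs + n_bad + b
                nonmito_total = int(X[ci, ~mito].sum())
                target_mito = int(np.ceil(0.3 / 0.7 * max(nonmito_total, 1)))
                X[ci, mito_idx] = 0
                X[ci, mito_idx] += rng.multinomial(
                    target_mito, np.ones(len(mito_idx)) / len(mito_idx)
                )
                high_mito_cells.append(cell_ids[ci])

    qc_label = np.array(["ok"] * len(cell_ids), dtype=object)
    qc_label[[cell_ids.index(c) for c in low_gene_cells]] = "low_genes"
    qc_label[[cell_ids.index(c) for c in high_mito_cells]] = "high_mito"
    obs = pd.DataFrame({"cell_type": labels, "qc_label": qc_label}, index=cell_ids)
    var = pd.DataFrame({"mito": mito}, index=gene_ids)
    adata = AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
    truth_part = {
        "elevated_genes": {t: sorted(elevated[t]) for t in types},
        "qc_cells": {"low_genes": low_gene_cells, "high_mito": high_mito_cells},
    }
    return adata, truth_part


# ---------------------------------------------------------------------------
# orchestration


def simulate(config: SimConfig | None = None) -> SimResult:
    """Run all generators with independent child streams of ``config.seed``."""
    config = config or SimConfig()
    config.validate()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(5)]
    rng_genes, rng_peaks, rng_ld, rng_hic, rng_sc = streams
    genes = gen_genes(config, rng_genes)
    peaks, lib, sample_meta, t_peaks = gen_peaks(config, genes, rng_peaks)
    tags, ld_df, t_ld = gen_ld(config, genes, t_peaks["cre_intervals"], rng_ld)
    matrices, t_hic = gen_contacts(config, genes, t_ld["snp_cres"], t_peaks["cre_intervals"], rng_hic)
    adata, t_sc = gen_scrna(config, genes, t_hic["elevated_seed"], rng_sc)
    truth = GroundTruth(
        specific_cres=t_peaks["specific_cres"],
        cre_intervals=t_peaks["cre_intervals"],
        tag_map=t_ld["tag_map"],
        snp_cres=t_ld["snp_cres"],
        tag_classes=t_ld["tag_classes"],
        loops=t_hic["loops"],
        elevated_genes=t_sc["elevated_genes"],
        qc_cells=t_sc["qc_cells"],
    )
    return SimResult(
        config=config,
        genes=genes,
        peaks=peaks,
        library_sizes=lib,
        sample_meta=sample_meta,
        tags=tags,
        ld=ld_df,
        contact_matrices=matrices,
        adata=adata,
        truth=truth,
    )


def write_all(sim: SimResult, out_dir: str | Path) -> Path:
    """Write every generated input in its on-disk exchange format."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "ld").mkdir(exist_ok=True)
    (out / "contacts").mkdir(exist_ok=True)
    (out / "scrna").mkdir(exist_ok=True)
    tssbed = sim.genes.assign(start=sim.genes["tss"], end=sim.genes["tss"] + 1)
    tssbed[["chrom", "start", "end", "gene_id", "mito", "strand"]].to_csv(
        out / "genes.bed", sep="\t", index=False, header=False
    )
    for sid, df in sim.peaks.items():
        df[["chrom", "start", "end"]].to_csv(out / "peaks" / f"{sid}.bed", sep="\t", index=False, header=False)
        df.to_csv(out / "peaks" / f"{sid}.counts.tsv", sep="\t", index=False)
    sim.library_sizes.rename_axis("sample_id").to_csv(out / "library_sizes.tsv", sep="\t")
    sim.sample_meta.to_csv(out / "sample_meta.tsv", sep="\t", index=False)
    sim.tags.to_csv(out / "tags.tsv", sep="\t", index=False)
    for pop, sub in sim.ld.groupby("population"):
        sub.to_csv(out / "ld" / f"{pop}.tsv", sep="\t", index=False)
    for (line, chrom), cm in sim.contact_matrices.items():
        cm.triplets.to_csv(out / "contacts" / f"{line}.{chrom}.tsv", sep="\t", index=False)
    mmwrite(str(out / "scrna" / "counts.mtx"), sparse.coo_matrix(sim.adata.X))
    sim.adata.obs.rename_axis("cell_id").to_csv(out / "scrna" / "cells.tsv", sep="\t")
    sim.adata.var.rename_axis("gene_id").to_csv(out / "scrna" / "genes.tsv", sep="\t")
    (out / "ground_truth.json").write_text(sim.truth.to_json() + "\n")
    cfg = asdict(sim.config)
    cfg["genome"] = [list(g) for g in sim.config.genome]
    cfg["loop_dist_range"] = list(sim.config.loop_dist_range)
    (out / "config.json").write_text(json.dumps(cfg, indent=1) + "\n")
    return out
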