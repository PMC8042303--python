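import io

import numpy as np
import pandas as pd
import pytest
from importlib import resources

from crelink import integration as itg
from crelink.catalog import CreCatalog
from crelink.pipeline import match_catalog_to_truth


def toy_catalog():
    cres = pd.DataFrame(
        [
            ("cre_a", "chr6", 30889572, 30895783),   # printed chr6:30889573-30895783
            ("cre_b", "chr1", 160315749, 160319868),  # printed chr1:160315750-160319868
        ],
        columns=["cre_id", "chrom", "start", "end"],
    )
    return CreCatalog(cres=cres)


def toy_calls():
    return pd.DataFrame(
        {"cre_id": ["cre_a", "cre_b"], "cell_type": ["Epithelial", "Myeloid"],
         "fdr": [2.35e-3, 3.07e-2]}
    ).set_index("cre_id", drop=False)


def expanded(rows):
    return pd.DataFrame(rows, columns=["parent_tag", "snp_id", "chrom", "pos",
                                       "n_supporting_populations", "r2_by_population", "is_tag"])


class TestOverlap:
    def test_published_ddr1_locus_snp_contained(self):
        exp = expanded([("chr6.30882415", "chr6.30894965", "chr6", 30894965, 3, {}, False)])
        out = itg.overlap_snps_cres(exp, toy_catalog(), toy_calls())
        assert len(out) == 1
        assert out["cre_id"].iloc[0] == "cre_a"
        assert out["cell_type"].iloc[0] == "Epithelial"

    def test_published_cd84_locus_two_snps_one_tag(self):
        exp = expanded([
            ("chr1.160210727", "chr1.160317021", "chr1", 160317021, 3, {}, False),
            ("chr1.160210727", "chr1.160317619", "chr1", 160317619, 3, {}, False),
        ])
        out = itg.overlap_snps_cres(exp, toy_catalog(), toy_calls())
        assert len(out) == 2
        assert out["tag_id"].nunique() == 1

    @pytest.mark.parametrize("pos, hit", [
        (30889573, True),   # printed 1-based start, inclusive
        (30889572, False),  # one bp before
        (30895783, True),   # printed 1-based end, inclusive
        (30895784, False),  # one bp past the end
    ])
    def test_containment_boundaries_1based_inclusive(self, pos, hit):
        exp = expanded([("chr6.1", f"chr6.{pos}", "chr6", pos, 3, {}, False)])
        out = itg.overlap_snps_cres(exp, toy_catalog(), toy_calls())
        assert (len(out) == 1) == hit


class TestRollup:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["tag_id", "snp_id", "cre_id", "cell_type"])

    def test_counts_and_percentages(self):
        tags = pd.DataFrame({"tag_id": [f"chr1.{i}" for i in range(10)]})
        assoc = self._assoc([
            ("chr1.0", "s1", "c1", "Myeloid"),
            ("chr1.1", "s2", "c2", "constitutive"),
            ("chr1.1", "s3", "c3", "Myeloid"),  # specific wins over constitutive
            ("chr1.2", "s4", "c4", "constitutive"),
        ])
        out = itg.tag_rollup(assoc, tags)
        assert out["n_linked"] == 3
        assert out["n_specific_linked"] == 2
        assert out["n_constitutive_only"] == 1
        assert out["pct_linked"] == 30.0

    def test_duplicate_records_do_not_inflate(self):
        tags = pd.DataFrame({"tag_id": ["chr1.0"]})
        assoc = self._assoc([("chr1.0", "s1", "c1", "Myeloid")] * 3)
        assert itg.tag_rollup(assoc, tags)["n_linked"] == 1

    def test_no_associations(self):
        tags = pd.DataFrame({"tag_id": ["chr1.0"]})
        out = itg.tag_rollup(self._assoc([]), tags)
        assert out["n_linked"] == 0 and out["pct_linked"] == 0.0

    def test_zero_tags_rejected(self):
        with pytest.raises(ValueError):
            itg.tag_rollup(self._assoc([]), pd.DataFrame({"tag_id": []}))


class TestPercentage:
    @pytest.mark.parametrize("n, d, want", [
        (45706, 86312, 52.95),
        (62, 286, 21.68),
        (1, 3, 33.33),
        (1, 8, 12.5),
    ])
    def test_half_up_two_decimals(self, n, d, want):
        assert itg.percentage(n, d) == want


class TestInferTargets:
    def _union(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "gene_id", "distal_bin", "support",
                                           "n_support", "distance"])

    def test_ddr1_style_assignment(self):
        assoc = pd.DataFrame([{
            "tag_id": "chr6.30882415", "snp_id": "chr6.30894965", "chrom": "chr6",
            "pos": 30894965, "cre_id": "cre_a", "cre_start": 30889572, "cre_end": 30895783,
            "cell_type": "Epithelial", "fdr": 2.35e-3,
        }])
        distal_bin = 30889572 // 5000  # overlaps the cRE start
        union = self._union([("chr6", "DDR1", distal_bin, "CL_A,CL_B", 2, 50_000)])
        out = itg.infer_targets(assoc, union)
        assert out["gene_id"].tolist() == ["DDR1"]
        assert out["cell_type"].iloc[0] == "Epithelial"
        assert out["distance"].iloc[0] == 50_000

    def test_constitutive_cres_excluded(self):
        assoc = pd.DataFrame([{
            "tag_id": "t", "snp_id": "s", "chrom": "chr1", "pos": 5,
            "cre_id": "c", "cre_start": 0, "cre_end": 5000,
            "cell_type": "constitutive", "fdr": 0.5,
        }])
        union = self._union([("chr1", "G1", 0, "A", 1, 100_000)])
        assert len(itg.infer_targets(assoc, union)) == 0

    def test_no_overlapping_distal_bin_no_assignment(self):
        assoc = pd.DataFrame([{
            "tag_id": "t", "snp_id": "s", "chrom": "chr1", "pos": 5,
            "cre_id": "c", "cre_start": 0, "cre_end": 5000,
            "cell_type": "Myeloid", "fdr": 0.01,
        }])
        union = self._union([("chr1", "G1", 10, "A", 1, 100_000)])
        assert len(itg.infer_targets(assoc, union)) == 0

    def test_no_orphan_targets_on_simulator(self, pipeline_default):
        res = pipeline_default
        assert set(res.targets["cre_id"]) <= set(res.associations["cre_id"])


class TestFixtureAndReport:
    def test_fixture_parses_to_28_distinct_tags(self):
        df = itg.load_table1_fixture()
        assert df["tag_snp"].nunique() == 28
        assert len(df) == 41

    def test_round_trip_byte_identical(self):
        raw = resources.files("crelink.data").joinpath("table1.tsv").read_text()
        rebuilt = itg.format_table1(itg.load_table1_fixture())
        buf = io.StringIO()
        rebuilt.to_csv(buf, sep="\t", index=False)
        assert buf.getvalue() == raw

    def test_empty_inputs_headers_only(self):
        tags = pd.DataFrame({"tag_id": ["chr1.1"], "rsid": ["rs1"], "pvalue": [1e-7],
                             "trait": ["t"], "source": ["s"]})
        assoc = pd.DataFrame(columns=["tag_id", "snp_id", "chrom", "pos", "cre_id",
                                      "cre_start", "cre_end", "cell_type", "fdr"])
        targets = pd.DataFrame(columns=["tag_id", "cre_id", "chrom", "cre_start", "cre_end",
                                        "cell_type", "fdr", "gene_id", "support", "n_support",
                                        "distance"])
        z = pd.DataFrame(columns=["Myeloid", "Epithelial"])
        rep = itg.build_report(assoc, targets, tags, z)
        assert len(rep["table1"]) == 0 and len(rep["table2"]) == 0

    def test_planted_links_appear_in_report(self, pipeline_default, sim_default):
        res = pipeline_default
        rep = itg.build_report(res.associations, res.targets, sim_default.tags, res.z)
        mapping = match_catalog_to_truth(res.catalog, sim_default.truth)
        inv = {v: k for k, v in mapping.items()}
        planted = {(l["tag"], l["gene"]) for l in sim_default.truth.loops}
        got = set(zip(res.targets["tag_id"], res.targets["gene_id"]))
        assert planted <= got
        assert len(rep["table2"]) >= len(planted)
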