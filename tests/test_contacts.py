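import numpy as np
import pandas as pd
import pytest

from crelink import contacts as ctc


def make_matrix(triplets, chrom_length=2_000_000, line="CL", chrom="chr1"):
    tri = pd.DataFrame(triplets, columns=["bin_i", "bin_j", "count"])
    return ctc.ContactMatrix(cell_line=line, chrom=chrom, chrom_length=chrom_length, triplets=tri)


class TestExpectedDecay:
    def test_power_law_recovered(self):
        n_bins = 400
        rows = []
        for k in range(3, 201):
            c = 1000.0 / k
            rows += [(i, i + k, c) for i in range(n_bins - k)]
        cm = make_matrix(rows)
        decay = ctc.expected_decay(cm)
        assert np.all(np.diff(decay["mu"].to_numpy()) <= 1e-9)
        ks = decay["k"].to_numpy()
        assert np.allclose(decay["mu"], 1000.0 / ks, rtol=1e-6)

    def test_constant_counts_give_constant_mu(self):
        n_bins = 400
        rows = [(i, i + k, 5) for k in range(3, 201) for i in range(n_bins - k)]
        decay = ctc.expected_decay(make_matrix(rows))
        assert np.allclose(decay["mu"], 5.0)

    def test_structural_zeros_count_in_stratum_mean(self):
        # one count of 10 at k=3 over n-3 possible pairs
        cm = make_matrix([(0, 3, 10)], chrom_length=100_000)
        decay = ctc.expected_decay(cm)
        n_bins = cm.n_bins
        assert decay.loc[decay["k"] == 3, "mu"].iloc[0] <= 10 / (n_bins - 3) + 1e-9

    def test_empty_matrix_rejected(self):
        with pytest.raises(ctc.ContactError):
            ctc.expected_decay(make_matrix([]))


class TestCallSignificant:
    def test_zero_observed_never_significant(self):
        rows = [(i, i + 3, 4) for i in range(100)] + [(0, 10, 0)]
        cm = make_matrix(rows)
        out = ctc.call_significant(cm, q_thresh=0.5)
        assert not ((out["bin_i"] == 0) & (out["bin_j"] == 10)).any()

    def test_short_range_pairs_excluded(self):
        rows = [(i, i + 2, 500) for i in range(100)] + [(i, i + 3, 4) for i in range(100)]
        cm = make_matrix(rows)
        out = ctc.call_significant(cm, q_thresh=0.99)
        assert (out["distance"] >= 15_000).all()

    def test_planted_spike_detected(self):
        rng = np.random.default_rng(0)
        n_bins = 300
        rows = []
        for k in range(3, 101):
            counts = rng.poisson(50.0 / k, n_bins - k)
            rows += [(i, i + k, c) for i, c in enumerate(counts) if c > 0]
        rows.append((10, 30, 200))  # k=20, mu=2.5, enormous excess
        out = ctc.call_significant(make_matrix(rows, chrom_length=1_500_000))
        assert ((out["bin_i"] == 10) & (out["bin_j"] == 30)).any()

    def test_bh_against_brute_force_oracle(self):
        from test_specificity import brute_force_bh

        rng = np.random.default_rng(1)
        n_bins = 200
        rows = []
        for k in range(3, 51):
            counts = rng.poisson(20.0 / k, n_bins - k)
            rows += [(i, i + k, c) for i, c in enumerate(counts) if c > 0]
        cm = make_matrix(rows, chrom_length=1_000_000)
        decay = ctc.expected_decay(cm)
        out = ctc.call_significant(cm, decay, q_thresh=1.1)  # keep everything
        # brute-force BH over the same universe: explicit p-vector with ones
        mu = decay.set_index("k")["mu"]
        kmin, kmax = 3, min(200, cm.n_bins - 1)
        pfull = []
        obs_index = {}
        tri = cm.triplets
        for rec in tri.itertuples(index=False):
            k = rec.bin_j - rec.bin_i
            if kmin <= k <= kmax and rec.count > 0:
                obs_index[(rec.bin_i, rec.bin_j)] = len(pfull)
                from scipy import stats

                pfull.append(stats.poisson.sf(rec.count - 1, mu.loc[k]))
        m_universe = sum(cm.n_bins - k for k in range(kmin, kmax + 1))
        pfull += [1.0] * (m_universe - len(pfull))
        qfull = brute_force_bh(pfull)
        for rec in out.itertuples(index=False):
            assert rec.q == pytest.approx(qfull[obs_index[(rec.bin_i, rec.bin_j)]])


class TestAnchorPromoters:
    def _contacts(self):
        return pd.DataFrame(
            [{"cell_line": "CL", "chrom": "chr1", "bin_i": 2, "bin_j": 40,
              "observed": 9, "expected": 1.0, "distance": 190_000, "p": 1e-9, "q": 1e-6}]
        )

    @pytest.mark.parametrize(
        "tss, anchored",
        [(12_400, True), (17_400, True), (17_600, False), (7_600, True), (7_400, False)],
    )
    def test_window_boundaries_around_bin_2(self, tss, anchored):
        tss_df = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [tss]})
        out = ctc.anchor_promoters(self._contacts(), tss_df)
        got = ((out["gene_id"] == "g") & (out["promoter_bin"] == 2)).any()
        assert got == anchored

    def test_double_promoter_contact_yields_both_genes(self):
        tss_df = pd.DataFrame({"gene_id": ["gA", "gB"], "chrom": ["chr1", "chr1"],
                               "tss": [12_000, 201_000]})
        out = ctc.anchor_promoters(self._contacts(), tss_df)
        assert set(out["gene_id"]) == {"gA", "gB"}
        assert len(out) == 2


class TestUnion:
    def _pi(self, line, gene="g", distal=40):
        return pd.DataFrame([{"cell_line": line, "chrom": "chr1", "gene_id": gene,
                              "promoter_bin": 2, "distal_bin": distal, "distance": 190_000}])

    def test_single_line_support(self):
        out = ctc.union_interactions([self._pi("A")])
        assert out["support"].iloc[0] == "A" and out["n_support"].iloc[0] == 1

    def test_same_pair_all_lines_collapses(self):
        out = ctc.union_interactions([self._pi(l) for l in "ABCD"])
        assert len(out) == 1
        assert out["support"].iloc[0] == "A,B,C,D"

    def test_disjoint_inputs_add(self):
        out = ctc.union_interactions([self._pi("A", gene="g1"), self._pi("B", gene="g2")])
        assert len(out) == 2

    def test_idempotent_and_order_invariant(self):
        a, b = self._pi("A"), self._pi("B", distal=50)
        u1 = ctc.union_interactions([a, b])
        u2 = ctc.union_interactions([b, a])
        pd.testing.assert_frame_equal(u1, u2)
        pd.testing.assert_frame_equal(ctc.union_interactions([u1.assign(cell_line=u1["support"])]).drop(columns=["support", "n_support"]),
                                      u1.drop(columns=["support", "n_support"]))


class TestDistanceSummary:
    def test_mean(self):
        df = pd.DataFrame({"distance": [100_000, 300_000]})
        out = ctc.distance_summary({"A": df})
        assert out["A"] == 200_000

    def test_empty_rejected(self):
        with pytest.raises(ctc.ContactError):
            ctc.distance_summary({"A": pd.DataFrame({"distance": []})})

    def test_simulator_mean_within_planted_range(self, pipeline_default, sim_default):
        dists = [l["distance"] for l in sim_default.truth.loops]
        per_line = {k: v for k, v in pipeline_default.significant.items() if len(v)}
        means = ctc.distance_summary(per_line)
        assert (means >= min(dists)).all() and (means <= max(dists)).all()
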