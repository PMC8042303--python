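import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crelink import catalog as cat


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def tss_df(positions, chrom="chr1"):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(positions))],
                         "chrom": chrom, "tss": positions})


class TestFilterDistal:
    @pytest.mark.parametrize(
        "peak, tss, kept",
        [
            (("chr1", 5000, 5200), 1000, True),   # gap 3800 > 2500
            (("chr1", 0, 100), 50, False),        # TSS inside peak
            (("chr1", 0, 100), 2600, True),       # boundary: end + 2500 exclusive
            (("chr1", 0, 100), 2599, False),      # just inside the window
            (("chr1", 5000, 5200), 2499, True),   # just outside the window
            (("chr1", 5000, 5200), 2500, False),  # start - 2500 inclusive edge
        ],
    )
    def test_promoter_window_boundaries(self, peak, tss, kept):
        out = cat.filter_distal(peaks_df([peak]), tss_df([tss]))
        assert (len(out) == 1) == kept

    def test_empty_tss_returns_all_with_warning(self):
        with pytest.warns(UserWarning):
            out = cat.filter_distal(peaks_df([("chr1", 0, 100)]), tss_df([]))
        assert len(out) == 1

    def test_idempotent(self):
        peaks = peaks_df([("chr1", 0, 100), ("chr1", 5000, 5200), ("chr2", 10, 400)])
        tss = tss_df([50, 900])
        once = cat.filter_distal(peaks, tss)
        twice = cat.filter_distal(once, tss)
        pd.testing.assert_frame_equal(once, twice)


class TestMergeAndStitch:
    def test_gap_within_stitch_joins(self):
        out = cat.merge_and_stitch([peaks_df([("chr1", 0, 100), ("chr1", 2000, 2100)])])
        assert out[["start", "end"]].to_numpy().tolist() == [[0, 2100]]

    def test_gap_beyond_stitch_stays_split(self):
        out = cat.merge_and_stitch([peaks_df([("chr1", 0, 100), ("chr1", 3200, 3300)])])
        assert len(out) == 2

    def test_boundary_gap_exactly_3000_joins(self):
        out = cat.merge_and_stitch([peaks_df([("chr1", 0, 100), ("chr1", 3100, 3300)])])
        assert len(out) == 1

    def test_single_peak_identity(self):
        out = cat.merge_and_stitch([peaks_df([("chr1", 10, 20)])])
        assert out[["chrom", "start", "end"]].iloc[0].tolist() == ["chr1", 10, 20]

    def test_empty_input(self):
        assert len(cat.merge_and_stitch([])) == 0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 50_000), st.integers(1, 4000)),
            min_size=1,
            max_size=30,
        )
    )
    def test_idempotent_and_gaps_exceed_stitch(self, raw):
        peaks = peaks_df([("chr1", s, s + w) for s, w in raw])
        out = cat.merge_and_stitch([peaks])
        again = cat.merge_and_stitch([out[["chrom", "start", "end"]]])
        assert out[["chrom", "start", "end"]].equals(again[["chrom", "start", "end"]])
        gaps = out["start"].to_numpy()[1:] - out["end"].to_numpy()[:-1]
        assert (gaps > 3000).all()


class TestRpm:
    def test_definition(self):
        counts = pd.DataFrame({"s1": [5, 0, 250]}, index=["a", "b", "c"])
        lib = pd.Series({"s1": 1_000_000})
        out = cat.quantify_rpm(counts, lib)
        assert out["s1"].tolist() == [5.0, 0.0, 250.0]

    def test_scaling(self):
        counts = pd.DataFrame({"s1": [250]})
        assert cat.quantify_rpm(counts, pd.Series({"s1": 5_000_000}))["s1"].iloc[0] == 50.0

    def test_zero_library_names_sample(self):
        counts = pd.DataFrame({"bad_sample": [1]})
        with pytest.raises(cat.CatalogError, match="bad_sample"):
            cat.quantify_rpm(counts, pd.Series({"bad_sample": 0}))

    def test_total_rpm_bounded_by_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, size=(50, 3)), columns=list("abc"))
        lib = pd.Series({"a": 10_000, "b": 20_000, "c": 30_000})
        out = cat.quantify_rpm(counts, lib)
        assert (out.sum(axis=0) <= 1_000_000 + 1e-6).all()


class TestQuantileNormalize:
    def test_hand_computed_reference(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = cat.quantile_normalize(m)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(cat.quantile_normalize(m), m)

    def test_ties_share_mean_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = cat.quantile_normalize(m)
        # tied entries of column a share the mean of ref[0:2]
        assert out["a"].iloc[0] == out["a"].iloc[1]

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.floats(0, 1e6, allow_nan=False, width=32), min_size=4, max_size=4,
                unique=True,
            ),
            min_size=2,
            max_size=5,
        )
    )
    def test_tie_free_columns_share_sorted_values(self, cols):
        m = pd.DataFrame({f"c{i}": v for i, v in enumerate(cols)}).astype(float)
        out = cat.quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for c in out.columns:
            assert np.allclose(np.sort(out[c].to_numpy()), ref)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(0, 100, allow_nan=False, width=16), min_size=5, max_size=5),
            min_size=2,
            max_size=4,
        )
    )
    def test_rank_order_preserved_within_columns(self, cols):
        m = pd.DataFrame({f"c{i}": v for i, v in enumerate(cols)}).astype(float)
        out = cat.quantile_normalize(m)
        for c in out.columns:
            orig = m[c].to_numpy()
            new = out[c].to_numpy()
            for i in range(len(orig)):
                for j in range(len(orig)):
                    if orig[i] < orig[j]:
                        assert new[i] <= new[j]


class TestSampleCorrelation:
    def test_self_and_negation(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [-1.0, -2.0, -3.0]})
        out = cat.sample_correlation(m)
        assert out.loc["a", "a"] == pytest.approx(1.0)
        assert out.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_is_missing(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        out = cat.sample_correlation(m)
        assert np.isnan(out.loc["a", "b"])

    def test_within_type_exceeds_between_type_on_planted_data(self, pipeline_default, sim_default):
        corr = cat.sample_correlation(pipeline_default.catalog.activity)
        labels = sim_default.sample_meta.set_index("sample_id")["cell_type"]
        same, diff = [], []
        cols = corr.columns
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                (same if labels[a] == labels[b] else diff).append(corr.loc[a, b])
        assert np.mean(same) > np.mean(diff)


def test_coord_conversion_round_trip():
    chrom, start, end = cat.parse_coord_1based("chr6:30889573-30895783")
    assert (start, end) == (30889572, 30895783)
    assert cat.coord_1based(chrom, start, end) == "chr6:30889573-30895783"
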