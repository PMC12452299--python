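import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xresponse.annotations_io import CountMatrix
from xresponse.diffexpr import (
    benjamini_hochberg,
    classify_degs,
    fc_from_fpkm,
    filter_expressed,
    fpkm,
    nb_wald_test,
    percent_reduction,
    size_factors,
    tpm,
)
from xresponse.synthetic import SimulationConfig, simulate_annotation, simulate_counts


def _cm(counts: pd.DataFrame, n_ctrl: int, n_def: int) -> CountMatrix:
    meta = pd.DataFrame(
        {
            "condition": ["control"] * n_ctrl + ["deficient"] * n_def,
            "replicate": list(range(1, n_ctrl + 1)) + list(range(1, n_def + 1)),
        },
        index=counts.columns,
    )
    return CountMatrix(counts=counts, sample_meta=meta)


class TestSizeFactors:
    def test_doubled_column_forces_sqrt2_factors(self):
        c = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc"))
        sf = size_factors(c)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_columns_give_unit_factors(self):
        c = pd.DataFrame({"s1": [5, 7, 9], "s2": [5, 7, 9]}, index=list("abc"))
        assert size_factors(c).to_numpy() == pytest.approx([1.0, 1.0])

    def test_all_zero_gene_excluded_from_reference(self):
        base = pd.DataFrame({"s1": [10, 20], "s2": [10, 20]}, index=list("ab"))
        with_zero = pd.concat([base, pd.DataFrame({"s1": [0], "s2": [0]}, index=["z"])])
        pd.testing.assert_series_equal(size_factors(base), size_factors(with_zero))

    def test_no_eligible_gene_advises_fallback(self):
        c = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]}, index=list("ab"))
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(c)
        assert (size_factors(c, allow_pseudo_reference=True) > 0).all()

    @given(scale=st.floats(min_value=0.25, max_value=4.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        """Scaling one sample by c scales its factor by c relative to the rest
        (the geometric-mean reference shifts all factors by a common c^(1/n))."""
        rng = np.random.default_rng(7)
        c = pd.DataFrame(rng.poisson(50, (30, 3)).astype(float) + 1, columns=["a", "b", "c"])
        sf = size_factors(c)
        scaled = c.copy()
        scaled["b"] = scaled["b"] * scale
        sf2 = size_factors(scaled)
        assert (sf2["b"] / sf2["a"]) == pytest.approx(scale * sf["b"] / sf["a"], rel=1e-9)
        assert (sf2["c"] / sf2["a"]) == pytest.approx(sf["c"] / sf["a"], rel=1e-9)


class TestExpressionUnits:
    def test_tpm_example_and_column_sum(self):
        c = pd.DataFrame({"s": [10, 10]}, index=["g1", "g2"])
        L = pd.Series([1000, 2000], index=["g1", "g2"])
        t = tpm(c, L)
        assert t["s"].to_numpy() == pytest.approx([666666.67, 333333.33], abs=0.01)
        assert t["s"].sum() == pytest.approx(1e6, rel=1e-9)

    def test_single_gene_tpm_is_million(self):
        t = tpm(pd.DataFrame({"s": [7]}, index=["g"]), pd.Series([500], index=["g"]))
        assert t.loc["g", "s"] == pytest.approx(1e6)

    def test_tpm_scale_invariance(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.poisson(20, (10, 2)) + 1, index=[f"g{i}" for i in range(10)])
        L = pd.Series(rng.integers(500, 5000, 10), index=c.index)
        pd.testing.assert_frame_equal(tpm(c, L), tpm(2 * c, L))

    def test_fpkm_formula(self):
        c = pd.DataFrame({"s": [100]}, index=["g"])
        out = fpkm(c, pd.Series([2000], index=["g"]), pd.Series([1_000_000], index=["s"]))
        assert out.loc["g", "s"] == pytest.approx(1e9 * 100 / (2000 * 1e6))

    def test_all_zero_sample_rejected(self):
        c = pd.DataFrame({"s": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="all-zero"):
            tpm(c, pd.Series([100, 100], index=c.index))


class TestPercentReduction:
    @pytest.mark.parametrize(
        "ctrl,defi,expected", [(100, 8, 92.0), (100, 100, 0.0), (100, 40, 60.0), (100, 150, -50.0)]
    )
    def test_reduction_values(self, ctrl, defi, expected):
        assert percent_reduction(ctrl, defi) == pytest.approx(expected)

    def test_zero_control_undefined(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 10.0)


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_matches_textbook_definition(self, pvals):
        p = np.array(pvals)
        got = benjamini_hochberg(p)
        # brute force: sort, p*m/rank, cumulative min from the largest rank
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_nan_propagates_without_affecting_others(self):
        got = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(got[1])
        np.testing.assert_allclose(got[[0, 2]], benjamini_hochberg([0.01, 0.04]))


class TestClassifyDegs:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [
            (0.60, 0.01, "up"),
            (0.58, 0.001, "none"),  # strict inequality at the boundary
            (-0.58, 0.001, "none"),
            (-1.2, np.nan, "none"),
            (-0.59, 0.049, "down"),
            (2.0, 0.05, "none"),  # alpha boundary is strict too
        ],
    )
    def test_threshold_semantics(self, lfc, padj, expected):
        det = pd.DataFrame(
            {"log2fc": [lfc], "pvalue": [0.01], "padj": [padj], "mean_expr": [10.0], "deg_class": ["none"]},
            index=["g"],
        )
        assert classify_degs(det).loc["g", "deg_class"] == expected

    @given(
        lfc=st.floats(min_value=-4, max_value=4),
        padj=st.floats(min_value=0, max_value=1),
        better_lfc=st.floats(min_value=0, max_value=2),
        better_p=st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_evidence(self, lfc, padj, better_lfc, better_p):
        """Decreasing padj or pushing log2fc away from zero never de-classifies."""

        def cls(l, p):
            det = pd.DataFrame(
                {"log2fc": [l], "pvalue": [p], "padj": [p], "mean_expr": [1.0], "deg_class": ["none"]},
                index=["g"],
            )
            return classify_degs(det).loc["g", "deg_class"]

        before = cls(lfc, padj)
        stronger = lfc + better_lfc if lfc >= 0 else lfc - better_lfc
        after = cls(stronger, padj * better_p)
        if before in ("up", "down"):
            assert after == before


class TestFcFromFpkm:
    def test_average_of_ratios_not_ratio_of_averages(self):
        assert fc_from_fpkm([2, 1], [4, 1]) == pytest.approx(1.5)
        assert fc_from_fpkm([1, 2], [2, 4]) == pytest.approx(2.0)
        assert fc_from_fpkm([1, 1], [1, 1]) == pytest.approx(1.0)

    def test_zero_wt_pair_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="WT FPKM = 0"):
            assert fc_from_fpkm([0, 2], [5, 4]) == pytest.approx(2.0)
        with pytest.warns(UserWarning):
            assert np.isnan(fc_from_fpkm([0.0], [5.0]))


class TestFilterExpressed:
    def test_inclusive_threshold(self):
        tab = pd.DataFrame({"s1": [1.0, 0.99, 3.0], "s2": [1.0, 0.99, 0.0]}, index=list("abc"))
        kept = filter_expressed(tab, threshold=1.0)
        assert list(kept) == ["a", "c"]  # mean 1.0 kept, 0.99 dropped, 1.5 kept

    def test_empty_table(self):
        tab = pd.DataFrame(columns=["s1"], dtype=float)
        assert len(filter_expressed(tab)) == 0


class TestNBWald:
    def test_null_type_one_error_calibrated(self):
        """Simulated null: raw p < 0.05 for ~5% of genes (0.05 +- 0.02)."""
        rates = []
        for seed in range(5):
            cfg = SimulationConfig(
                seed=300 + seed, scenario="null", n_autosomes=8, autosome_length=25_000_000,
                x_length=25_000_000,
            )
            ann, _, _ = simulate_annotation(cfg)
            cm, _ = simulate_counts(ann, cfg)
            det = nb_wald_test(cm)
            p = det["pvalue"].dropna()
            assert len(p) > 1500
            rates.append(float((p < 0.05).mean()))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_strong_effect_called_up(self):
        rng = np.random.default_rng(42)
        n = 400
        mu = rng.lognormal(4.5, 1.0, n)
        counts = np.column_stack(
            [rng.poisson(mu) for _ in range(3)] + [rng.poisson(mu) for _ in range(3)]
        )
        counts[0, 3:] = rng.poisson(500 * 4, 3)  # true log2fc = 2 at mean 500
        counts[0, :3] = rng.poisson(500, 3)
        cm = _cm(pd.DataFrame(counts, index=[f"g{i}" for i in range(n)],
                              columns=["c1", "c2", "c3", "d1", "d2", "d3"]), 3, 3)
        det = nb_wald_test(cm)
        assert det.loc["g0", "deg_class"] == "up"

    def test_all_zero_gene_has_missing_p(self, small_counts):
        counts = small_counts.counts.copy()
        counts.iloc[0] = 0
        cm = _cm(counts, 3, 3)
        det = nb_wald_test(cm)
        g = counts.index[0]
        assert np.isnan(det.loc[g, "pvalue"]) and np.isnan(det.loc[g, "padj"])
        assert det.loc[g, "deg_class"] == "none"

    def test_single_condition_rejected(self, small_counts):
        meta = small_counts.sample_meta.copy()
        meta["condition"] = "control"
        cm = CountMatrix(counts=small_counts.counts, sample_meta=meta)
        with pytest.raises(ValueError, match="2 samples per condition"):
            nb_wald_test(cm)
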