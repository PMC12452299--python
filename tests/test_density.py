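import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xresponse.density import (
    cross_dataset_correlation,
    deg_position_table,
    density_track,
    make_windows,
    midpoint,
    partial_correlation,
    pearson,
)


def _features(intervals, chrom="chrX"):
    return pd.DataFrame(
        [{"chrom": chrom, "start": s, "end": e} for s, e in intervals]
    )


class TestMidpoint:
    @pytest.mark.parametrize("s,e,expected", [(100, 200, 150), (100, 201, 150), (0, 2, 1)])
    def test_floor_rule(self, s, e, expected):
        assert midpoint(s, e) == expected

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            midpoint(5, 5)


class TestMakeWindows:
    def test_window_count_formula(self):
        w = make_windows(2_000_000)
        assert len(w) == 5
        assert list(w.starts) == [0, 250_000, 500_000, 750_000, 1_000_000]

    def test_exact_single_window(self):
        assert len(make_windows(1_000_000)) == 1

    def test_short_chromosome_truncated(self):
        w = make_windows(600_000)
        assert len(w) == 1 and w.size == 600_000

    @given(L=st.integers(1, 10**7), step=st.integers(1, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_count_matches_closed_form(self, L, step):
        window = step * 4
        w = make_windows(L, window, step)
        expected = 1 if L < window else (L - window) // step + 1
        assert len(w) == expected

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_windows(10**6, window=0)
        with pytest.raises(ValueError):
            make_windows(10**6, window=100, step=200)


class TestDensityTrack:
    def test_midpoint_counted_in_every_containing_window(self):
        w = make_windows(2_000_000)
        track = density_track(_features([(499_999, 500_001)]), w, "chrX")
        # midpoint 500000 lies in windows starting at 0, 250k and 500k
        assert list(track.values) == [1, 1, 1, 0, 0]

    def test_empty_features_all_zero(self):
        w = make_windows(2_000_000)
        assert density_track(_features([]), w, "chrX").values.sum() == 0

    def test_coverage_of_spanning_element_is_one(self):
        w = make_windows(1_000_000)
        track = density_track(_features([(0, 1_000_000)]), w, "chrX", mode="coverage")
        assert track.values[0] == pytest.approx(1.0)

    def test_nonoverlapping_counts_sum_to_features(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 4_000_000 - 10, 200)
        feats = _features([(int(s), int(s) + 10) for s in starts])
        w = make_windows(4_000_000, window=1_000_000, step=1_000_000)
        track = density_track(feats, w, "chrX")
        covered = (starts + 5) < w.starts[-1] + w.size
        assert track.values.sum() == covered.sum()

    def test_other_chromosomes_ignored(self):
        w = make_windows(1_000_000)
        feats = pd.concat([_features([(10, 30)]), _features([(10, 30)], chrom="chr1")])
        assert density_track(feats, w, "chrX").values.sum() == 1


class TestCorrelations:
    def test_pearson_perfect_and_constant(self):
        x = np.arange(10.0)
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="constant"):
            pearson(x, np.ones(10))

    def test_partial_correlation_closed_form(self):
        # r_xy = 0.9, r_xz = r_yz = 0.8 -> (0.9 - 0.64)/0.36 = 0.7222
        rng = np.random.default_rng(0)
        # impose the exact sample correlation via QR orthonormalization
        target = np.array([[1, 0.9, 0.8], [0.9, 1, 0.8], [0.8, 0.8, 1]])
        raw = rng.standard_normal((2000, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        x, y, z = (q @ np.linalg.cholesky(target).T).T
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(0.26 / 0.36, abs=1e-9)
        assert res.r == pytest.approx(0.7222, abs=1e-4)

    def test_uncorrelated_control_leaves_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        z = rng.normal(size=500)
        # whiten z against x and y exactly is unnecessary: compare closed forms
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert partial_correlation(x, y, z).r == pytest.approx(expected, abs=1e-12)

    def test_partial_matches_residual_regression_oracle(self):
        """r_xy.z equals the Pearson correlation of the least-squares
        residuals of x on z and y on z, on 100 random instances."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(10, 60)
            z = rng.normal(size=n)
            x = 0.5 * z + rng.normal(size=n)
            y = -0.3 * z + rng.normal(size=n)
            A = np.column_stack([np.ones(n), z])
            rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
            ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert partial_correlation(x, y, z).r == pytest.approx(oracle, abs=1e-10)

    @given(
        a=st.floats(0.1, 5), b=st.floats(-10, 10), c=st.floats(0.1, 5), d=st.floats(-10, 10)
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b, c, d):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = x * 0.5 + rng.normal(size=50)
        z = rng.normal(size=50)
        assert pearson(a * x + b, c * y + d).r == pytest.approx(pearson(x, y).r, abs=1e-9)
        assert partial_correlation(a * x + b, c * y + d, z).r == pytest.approx(
            partial_correlation(x, y, z).r, abs=1e-9
        )

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])
        with pytest.raises(ValueError):
            partial_correlation([1, 2, 3], [1, 2, 3], [0, 1, 2])


class TestDegPositions:
    def test_scatter_rows_and_highlight(self, tiny_annotation):
        det = pd.DataFrame(
            {
                "log2fc": [1.2, -0.9, 2.0, 0.1],
                "pvalue": [0.001] * 4,
                "padj": [0.001, 0.001, 0.001, 0.9],
                "mean_expr": [10.0] * 4,
                "deg_class": ["up", "down", "down", "none"],
            },
            index=["x1", "XIST", "a1", "b1"],
        )
        tab = deg_position_table(det, tiny_annotation, chrom="chrX")
        assert list(tab.index) == ["x1", "XIST"]  # sorted by position; a1 not on X
        assert tab.loc["x1", "position"] == 1100
        assert bool(tab.loc["XIST", "highlight"]) is True
        assert tab.loc["x1", "direction"] == "up"

    def test_no_x_degs_empty(self, tiny_annotation):
        det = pd.DataFrame(
            {"log2fc": [0.1], "pvalue": [0.5], "padj": [0.9], "mean_expr": [1.0], "deg_class": ["none"]},
            index=["x1"],
        )
        assert deg_position_table(det, tiny_annotation).empty


class TestCrossDataset:
    def test_identical_tracks_r_one(self):
        w = make_windows(3_000_000)
        t = density_track(_features([(10, 30), (1_200_000, 1_200_400)]), w, "chrX")
        assert cross_dataset_correlation(t, t).r == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        f = _features([(10, 30), (1_200_000, 1_200_400), (2_000_001, 2_000_010)])
        t1 = density_track(f, make_windows(3_000_000), "chrX")
        t2 = density_track(f, make_windows(3_000_000, step=500_000), "chrX")
        with pytest.raises(ValueError, match="grid"):
            cross_dataset_correlation(t1, t2)

    def test_independent_tracks_weakly_correlated(self):
        rng = np.random.default_rng(8)
        w = make_windows(150_000_000)  # ~600 windows
        rs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            fa = _features([(int(s), int(s) + 100) for s in rng.integers(0, 149_000_000, 3000)])
            fb = _features([(int(s), int(s) + 100) for s in rng.integers(1, 149_000_000, 3000)])
            ta = density_track(fa, w, "chrX")
            tb = density_track(fb, w, "chrX")
            rs.append(abs(cross_dataset_correlation(ta, tb).r))
        assert np.median(rs) < 0.15
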