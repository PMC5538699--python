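"""Anteroposterior profiles, agreement statistics, rank aggregation and the
Kruskal-Wallis / Tukey-Kramer model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ventprofile.geometry import PixelGrid
from ventprofile.pipeline import TidalImage
from ventprofile.profiles import (
    VentilationProfile,
    ap_profile,
    bland_altman,
    compare_models,
    image_correlation_2d,
    pooled_pearson,
    profile_rmse,
    rank_settings,
)


class TestApProfile:
    def test_mass_in_first_row(self):
        img = np.zeros((32, 32))
        img[0] = 1.0
        p = ap_profile(img, np.ones((32, 32), dtype=bool))
        assert p.values[0] == 100.0
        assert np.all(p.values[1:] == 0.0)

    def test_uniform_bands(self):
        p = ap_profile(np.ones((32, 32)), np.ones((32, 32), dtype=bool))
        assert np.allclose(p.values, 100.0 / 32)

    def test_highres_band_aggregation(self):
        img = np.zeros((128, 128))
        img[:64] = 1.0
        p = ap_profile(img, np.ones((128, 128), dtype=bool))
        assert np.allclose(p.values[:16], 6.25)
        assert np.all(p.values[16:] == 0.0)

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(4)
        img = rng.uniform(0.1, 1.0, (32, 32))
        mask = np.ones((32, 32), dtype=bool)
        assert np.allclose(
            ap_profile(img, mask).values, ap_profile(scale * img, mask).values
        )

    def test_zero_mass_error(self):
        with pytest.raises(ValueError):
            ap_profile(np.zeros((32, 32)), np.ones((32, 32), dtype=bool))

    def test_sums_to_100(self):
        rng = np.random.default_rng(9)
        p = ap_profile(rng.uniform(size=(64, 64)), rng.uniform(size=(64, 64)) > 0.3)
        assert p.values.sum() == pytest.approx(100.0, abs=1e-9)


class TestRmse:
    def test_identical(self):
        p = VentilationProfile(np.full(32, 100.0 / 32))
        assert profile_rmse(p, p) == 0.0

    def test_hand_value(self):
        a = np.zeros(32)
        a[0] = 100.0
        b = np.zeros(32)
        b[1] = 100.0
        v = profile_rmse(VentilationProfile(a), VentilationProfile(b))
        assert v == pytest.approx(25.0)

    def test_symmetry_and_mismatch(self):
        a = VentilationProfile(np.full(32, 100.0 / 32))
        rng = np.random.default_rng(1)
        w = rng.uniform(0.5, 1.5, 32)
        b = VentilationProfile(100.0 * w / w.sum())
        assert profile_rmse(a, b) == profile_rmse(b, a)
        with pytest.raises(ValueError):
            profile_rmse(a, VentilationProfile(np.full(16, 100.0 / 16)))


class TestPooledPearson:
    def test_proportional_pairs(self):
        pairs = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        assert pooled_pearson(pairs) == pytest.approx(1.0)

    def test_two_pass_formula_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 5.0, 200)
        y = 0.4 * x + rng.normal(0, 0.5, 200)
        pairs = np.column_stack([x, y])
        xm, ym = x.mean(), y.mean()
        r_oracle = np.sum((x - xm) * (y - ym)) / np.sqrt(
            np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)
        )
        assert pooled_pearson(pairs, filtered=False) == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_error(self):
        pairs = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError):
            pooled_pearson(pairs)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            pooled_pearson(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestBlandAltman:
    def test_identical_methods(self):
        pairs = np.column_stack([np.arange(1.0, 6.0), np.arange(1.0, 6.0)])
        bias, (lo, hi) = bland_altman(pairs)
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_both_zero_pairs_excluded(self):
        pairs = np.array([[0.0, 0.0]] * 10 + [[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        bias, _ = bland_altman(pairs)
        assert bias == 1.0  # the zero pairs do not drag the median to 0

    def test_quantile_interpolation_oracle(self):
        d = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        pairs = np.column_stack([np.ones(5), 1.0 + d])
        bias, (lo, hi) = bland_altman(pairs)
        assert bias == 0.0
        # linear interpolation between order statistics
        assert lo == pytest.approx(-1.9)
        assert hi == pytest.approx(1.9)

    def test_too_few_retained(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([[0.0, 0.0]] * 5 + [[1.0, 2.0]]))


class TestImageCorrelation:
    def _grid(self):
        ones = np.ones((32, 32), dtype=bool)
        return PixelGrid(bounds=(0, 0, 32, 32), body_mask=ones, lung_mask=ones, heart_mask=~ones)

    def test_self_and_affine(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(size=(128, 128))
        grid = self._grid()
        ref32 = ref.reshape(32, 4, 32, 4).mean(axis=(1, 3))
        eit = TidalImage(pixels=ref32, body_mask=grid.body_mask)
        assert image_correlation_2d(eit, ref, grid) == pytest.approx(1.0)
        eit2 = TidalImage(pixels=3.0 * ref32 + 1.0, body_mask=grid.body_mask)
        assert image_correlation_2d(eit2, ref, grid) == pytest.approx(1.0)

    def test_anticorrelated_checkerboard(self):
        grid = self._grid()
        board = np.indices((32, 32)).sum(axis=0) % 2 == 0
        eit = TidalImage(pixels=board.astype(float), body_mask=grid.body_mask)
        assert image_correlation_2d(eit, (~board).astype(float), grid) == pytest.approx(-1.0)

    def test_constant_error(self):
        grid = self._grid()
        eit = TidalImage(pixels=np.ones((32, 32)), body_mask=grid.body_mask)
        with pytest.raises(ValueError):
            image_correlation_2d(eit, np.ones((32, 32)), grid)


class TestRankSettings:
    def test_singleton(self):
        rows = pd.DataFrame(
            [{"setting": "a", "subject": 0, "correlation": 0.5}]
        )
        ranking = rank_settings(rows)
        assert list(ranking.setting) == ["a"]
        assert ranking.mean_rank.iloc[0] == 1.0

    def test_dominance(self):
        rows = pd.DataFrame(
            [
                {"setting": s, "subject": i, "correlation": c}
                for i, (ca, cb) in enumerate([(0.9, 0.5), (0.8, 0.6), (0.7, 0.1)])
                for s, c in (("good", ca), ("bad", cb))
            ]
        )
        ranking = rank_settings(rows)
        assert ranking.setting.iloc[0] == "good"

    def test_mean_rank_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for subj in range(3):
            for k in range(8):
                rows.append(
                    {"setting": f"s{k}", "subject": subj, "correlation": rng.uniform()}
                )
        df = pd.DataFrame(rows)
        ranking = rank_settings(df)
        # spreadsheet-style recomputation
        expect = {}
        for subj, grp in df.groupby("subject"):
            order = grp.sort_values("correlation", ascending=False)
            for rank, (_, row) in enumerate(order.iterrows(), start=1):
                expect.setdefault(row.setting, []).append(rank)
        expect = {k: np.mean(v) for k, v in expect.items()}
        got = dict(zip(ranking.setting, ranking.mean_rank))
        assert got == expect

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        rows = pd.DataFrame(
            [
                {"setting": f"s{k}", "subject": i, "correlation": rng.uniform()}
                for i in range(3)
                for k in range(5)
            ]
        )
        r1 = rank_settings(rows)
        rows2 = rows.assign(correlation=np.tanh(3.0 * rows.correlation))
        r2 = rank_settings(rows2)
        assert list(r1.setting) == list(r2.setting)
        assert np.allclose(r1.mean_rank, r2.mean_rank)


class TestCompareModels:
    def test_identical_groups(self):
        tbl = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        rep = compare_models(tbl)
        assert rep["H"] == pytest.approx(0.0, abs=1e-12)
        assert rep["p"] == pytest.approx(1.0)

    def test_hand_computed_h(self):
        tbl = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [101.0, 102.0, 103.0], "c": [201.0, 202.0, 203.0]}
        )
        rep = compare_models(tbl)
        # ranks 1-3, 4-6, 7-9: H = 12/(9*10) * (36+225+576)/3 - 3*10 = 7.2
        assert rep["H"] == pytest.approx(7.2)
        assert rep["df"] == 2
        assert rep["p"] == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_permutation_invariance(self):
        tbl = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [9.0, 7.0, 8.0]})
        tbl2 = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 8.0, 9.0]})
        assert compare_models(tbl)["H"] == pytest.approx(compare_models(tbl2)["H"])

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(ValueError):
            compare_models(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}))
        with pytest.raises(ValueError):
            compare_models(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_pairwise_p_detects_extreme_groups(self):
        tbl = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0, 5.0],
                "b": [1.5, 2.5, 3.5, 4.5, 5.5],
                "c": [101.0, 102.0, 103.0, 104.0, 105.0],
            }
        )
        rep = compare_models(tbl)
        assert rep["pairwise_p"].loc["a", "c"] < rep["pairwise_p"].loc["a", "b"]
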