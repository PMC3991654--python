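import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from acmap.groupstats import (
    StudyDesign,
    correlate_disability,
    dice,
    fit_glm,
    lesion_difference,
    lesion_probability_map,
    proportion_test,
    roi_median,
    smooth,
    svc_fwe,
    ttest_from_summary,
    welch_group_t,
)
from acmap.io import BinaryMask, Volume


def _vol(data, vox=2.0):
    return Volume(np.asarray(data, float), np.diag([vox, vox, vox, 1.0]))


class TestSmooth:
    def test_zero_fwhm_identity(self, rng):
        v = _vol(rng.normal(size=(8, 8, 8)))
        np.testing.assert_array_equal(smooth(v, 0.0).data, v.data)

    def test_constant_unchanged(self):
        v = _vol(np.full((9, 9, 9), 3.5))
        out = smooth(v, 4.0)
        np.testing.assert_allclose(out.data[2:-2, 2:-2, 2:-2], 3.5, atol=1e-6)

    def test_delta_halfmax_at_2mm(self):
        # 4 mm FWHM kernel on a 2 mm grid: half max exactly one voxel away
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        out = smooth(_vol(data, vox=2.0), 4.0).data
        ratio = out[8, 7, 7] / out[7, 7, 7]
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_mass_preserved(self, rng):
        data = np.zeros((16, 16, 16))
        data[5:11, 5:11, 5:11] = rng.random((6, 6, 6))
        out = smooth(_vol(data), 4.0)
        np.testing.assert_allclose(out.data.sum(), data.sum(), rtol=1e-6)

    def test_translation_commutes(self, rng):
        data = np.zeros((16, 16, 16))
        data[6:9, 6:9, 6:9] = rng.random((3, 3, 3))
        a = smooth(_vol(np.roll(data, 2, axis=0)), 4.0).data
        b = np.roll(smooth(_vol(data), 4.0).data, 2, axis=0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_negative_fwhm(self):
        with pytest.raises(ValueError):
            smooth(_vol(np.zeros((4, 4, 4))), -1.0)


class TestGLM:
    def _design(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        return np.column_stack(
            [np.ones(n), rng.integers(0, 2, n), rng.normal(45, 9, n), rng.integers(0, 2, n)]
        )

    def test_identical_groups_zero_t(self):
        x = self._design()
        y = np.tile(np.linspace(1, 2, 30), (len(x), 1))
        res = fit_glm(y, x, np.array([0, 1, 0, 0]))
        np.testing.assert_allclose(res.t, 0.0, atol=1e-10)

    def test_known_effect_and_scalar_oracle(self):
        rng = np.random.default_rng(5)
        x = self._design(seed=5)
        eps = rng.normal(0, 1, (len(x), 40))
        y = 2.0 * x[:, 1][:, None] + eps
        c = np.array([0, 1, 0, 0])
        res = fit_glm(y, x, c)
        assert np.mean(res.beta[1]) == pytest.approx(2.0, abs=0.2)
        # hand-rolled scalar OLS per voxel
        xtx_inv = np.linalg.inv(x.T @ x)
        for v in range(0, 40, 7):
            beta = xtx_inv @ x.T @ y[:, v]
            r = y[:, v] - x @ beta
            s2 = r @ r / (len(x) - x.shape[1])
            t = beta[1] / np.sqrt(s2 * xtx_inv[1, 1])
            assert res.t[v] == pytest.approx(t, abs=1e-10)

    def test_one_voxel_reduces_to_scalar_regression(self):
        x = self._design(seed=2)
        rng = np.random.default_rng(2)
        y = rng.normal(size=(len(x), 1))
        res = fit_glm(y, x, np.array([0, 1, 0, 0]))
        beta = np.linalg.lstsq(x, y[:, 0], rcond=None)[0]
        assert res.beta[1, 0] == pytest.approx(beta[1], abs=1e-12)

    def test_rank_deficiency(self):
        x = self._design()
        x[:, 3] = x[:, 1]
        with pytest.raises(ValueError):
            fit_glm(np.zeros((len(x), 3)), x, np.array([0, 1, 0, 0]))

    def test_study_design_wrapper(self):
        tab = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(8)],
                "group": ["healthy"] * 3 + ["RR"] * 3 + ["SP"] * 2,
                "age": np.arange(8) + 40.0,
                "gender": [0, 1] * 4,
            }
        )
        d = StudyDesign(tab)
        x, names = d.design_matrix()
        assert names[:3] == ["intercept", "RR", "SP"]
        c = d.contrast(names, {"RR": 1.0, "SP": -1.0})
        np.testing.assert_array_equal(c, [0, 1, -1, 0, 0])

    def test_design_validation(self):
        with pytest.raises(ValueError):
            StudyDesign(pd.DataFrame({"subject": ["a"], "group": ["weird"],
                                      "age": [40.0], "gender": [0]}))


class TestTTestFromSummary:
    def test_identical_summaries(self):
        t, df, p = ttest_from_summary(1.0, 1.0, 10, 1.0, 1.0, 10)
        assert t == 0.0 and p == 1.0

    def test_printed_age_p_healthy_rr(self):
        _, _, p = ttest_from_summary(44.60, 9.87, 20, 39.45, 8.98, 19)
        assert round(p, 2) == 0.10

    def test_printed_age_p_sp_rr(self):
        _, _, p = ttest_from_summary(49.34, 11.31, 15, 39.45, 8.98, 19)
        assert round(p, 2) == 0.01

    def test_healthy_sp_value_documented(self):
        # from the printed summaries the pooled two-tailed p is 0.1956
        _, _, p = ttest_from_summary(44.60, 9.87, 20, 49.34, 11.31, 15)
        assert p == pytest.approx(0.1956, abs=2e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.4, 17)
        for variant, equal_var in (("pooled", True), ("welch", False)):
            t, df, p = ttest_from_summary(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b),
                variant=variant,
            )
            ref = stats.ttest_ind(a, b, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1, 1, 1, 1, 1, 10)
        with pytest.raises(ValueError):
            ttest_from_summary(1, -1, 5, 1, 1, 10)


class TestWelchAdjusted:
    def test_matches_scipy_without_nuisance(self, rng):
        y = rng.normal(size=(20, 9))
        ga = np.zeros(20, bool)
        ga[:8] = True
        gb = ~ga
        t, df = welch_group_t(y, ga, gb)
        ref = stats.ttest_ind(y[ga], y[gb], equal_var=False)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)


class TestSVCFWE:
    def _setup(self, n=20, vox=60, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = np.column_stack([np.ones(n), np.r_[np.ones(n // 2), np.zeros(n - n // 2)],
                             rng.normal(45, 8, n)])
        y = rng.normal(size=(n, vox))
        y[: n // 2, : vox // 4] += effect
        return y, x, np.array([0, 1.0, 0])

    def test_effect_detected_in_roi_only(self):
        y, x, c = self._setup(effect=2.5, seed=1)
        res = svc_fwe(y, x, c, np.ones(60, bool), n_permutations=300, rng=0)
        assert res.significant[: 15].sum() > 0
        assert res.significant[15:].sum() == 0

    def test_self_contrast_no_significance(self, rng):
        y, x, _ = self._setup(seed=3)
        c = np.array([0.0, 0.0, 0.0])
        c[0] = 0.0  # contrast of a group against itself: all-zero weights
        res = svc_fwe(y, x, np.array([0, 0, 0.0]), np.ones(60, bool),
                      n_permutations=200, rng=1)
        assert res.significant.sum() == 0

    def test_too_few_permutations(self):
        y, x, c = self._setup()
        with pytest.raises(ValueError):
            svc_fwe(y, x, c, np.ones(60, bool), n_permutations=50)

    def test_type_one_error_calibrated_quick(self):
        # 60 null cohorts as a fast sanity check (full 200 in acceptance)
        hits = 0
        reps = 60
        for i in range(reps):
            y, x, c = self._setup(seed=100 + i)
            res = svc_fwe(y, x, c, np.ones(60, bool), n_permutations=199, rng=i)
            hits += int(res.significant.sum() > 0)
        assert stats.binomtest(hits, reps, 0.05).pvalue > 0.01


class TestROIAndCorrelation:
    def test_roi_median_constant(self):
        v = _vol(np.full((4, 4, 4), 7.0))
        labels = np.ones((4, 4, 4), int)
        assert roi_median(v, labels, 1) == 7.0

    def test_even_count_midpoint(self):
        data = np.zeros((4, 1, 1))
        data[:, 0, 0] = [1, 2, 3, 100]
        labels = np.ones((4, 1, 1), int)
        assert roi_median(_vol(data), labels, 1) == 2.5

    def test_against_sort_oracle(self, rng):
        data = rng.normal(size=(6, 6, 6))
        labels = rng.integers(0, 3, (6, 6, 6))
        for rid in (0, 1, 2):
            vals = np.sort(data[labels == rid])
            n = len(vals)
            oracle = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert roi_median(_vol(data), labels, rid) == pytest.approx(oracle, abs=1e-12)

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            roi_median(_vol(np.zeros((2, 2, 2))), np.zeros((2, 2, 2), int), 5)

    def test_perfect_linear_correlation(self):
        med = np.array([1.0, 2, 3, 4, 5])
        edss = 2 * med + 1
        age = np.array([40.0, 50, 45, 60, 55])
        gender = np.array([0, 1, 0, 1, 0])
        res = correlate_disability(med, edss, age, gender)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_generative_recovery(self):
        rng = np.random.default_rng(8)
        n = 200
        med = rng.normal(size=n)
        age = rng.normal(45, 9, n)
        noise = rng.normal(0, 0.5, n)
        edss = 1.5 * med + 0.02 * age + noise
        res = correlate_disability(med, edss, age, rng.integers(0, 2, n))
        signal_var = np.var(1.5 * med + 0.02 * age)
        expected_r2 = signal_var / (signal_var + 0.25)
        assert res.r2 == pytest.approx(expected_r2, abs=0.05)

    def test_null_calibration(self):
        rng = np.random.default_rng(9)
        n = 20
        crit = stats.t.ppf(0.975, n - 2)
        hits = 0
        sims = 1000
        for _ in range(sims):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            r = np.corrcoef(a, b)[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            hits += int(abs(t) > crit)
        assert stats.binomtest(hits, sims, 0.05).pvalue > 0.001

    def test_bonferroni(self):
        med = np.array([1.0, 2, 3, 4, 5, 6])
        edss = med + np.array([0.1, -0.2, 0.15, 0.0, -0.1, 0.05])
        res = correlate_disability(med, edss, np.arange(6.0), np.zeros(6), n_rois=10)
        assert res.pearson_p_bonferroni == pytest.approx(min(1.0, res.pearson_p * 10))


class TestLesionMaps:
    def _mask(self, data):
        return BinaryMask(np.asarray(data, np.uint8), np.eye(4))

    def test_shared_voxel(self):
        m = np.zeros((3, 3, 3))
        m[1, 1, 1] = 1
        lm = lesion_probability_map([self._mask(m)] * 4)
        assert lm.data[1, 1, 1] == 1.0
        assert lm.data.sum() == 1.0

    def test_one_of_four(self):
        z = np.zeros((3, 3, 3))
        m = z.copy()
        m[0, 0, 0] = 1
        lm = lesion_probability_map([self._mask(m)] + [self._mask(z)] * 3)
        assert lm.data[0, 0, 0] == 0.25

    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        masks = [self._mask(rng.random((4, 4, 4)) > 0.7) for _ in range(5)]
        d = lesion_difference(lesion_probability_map(masks), lesion_probability_map(masks))
        np.testing.assert_array_equal(d.data, 0.0)
        t = proportion_test(masks, masks)
        np.testing.assert_array_equal(t.data, 0.0)

    def test_empty_list(self):
        with pytest.raises(ValueError):
            lesion_probability_map([])


class TestDice:
    def _mask(self, data):
        return BinaryMask(np.asarray(data, np.uint8), np.eye(4))

    def test_identical(self):
        m = np.zeros((3, 3, 3))
        m[0] = 1
        assert dice(self._mask(m), self._mask(m)) == 1.0

    def test_disjoint(self):
        a = np.zeros((3, 3, 3))
        b = np.zeros((3, 3, 3))
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dice(self._mask(a), self._mask(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, :2, :] = 1  # 8 voxels
        b[0, 1:3, :] = 1  # 8 voxels, 4 shared
        assert dice(self._mask(a), self._mask(b)) == 0.5

    def test_both_empty(self):
        z = np.zeros((2, 2, 2))
        assert dice(self._mask(z), self._mask(z)) == 0.0

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            dice(self._mask(np.zeros((2, 2, 2))), self._mask(np.zeros((3, 3, 3))))


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_dice_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((5, 5, 5)) > 0.6
    b = rng.random((5, 5, 5)) > 0.6
    ma = BinaryMask(a.astype(np.uint8), np.eye(4))
    mb = BinaryMask(b.astype(np.uint8), np.eye(4))
    # brute-force set computation
    sa = {tuple(i) for i in np.argwhere(a)}
    sb = {tuple(i) for i in np.argwhere(b)}
    denom = len(sa) + len(sb)
    expected = 0.0 if denom == 0 else 2 * len(sa & sb) / denom
    assert dice(ma, mb) == pytest.approx(expected, abs=1e-12)
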