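import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from acmap.io import GradientTable
from acmap.multitensor import (
    DiffusionTensor,
    MultiTensorVoxel,
    classify_fibre_count,
    compute_fa,
    compute_md,
    fit_single_tensor,
    fit_two_tensor,
    predict_signal,
    predict_signals,
    rss,
    tensor_field_from_array,
    tensor_field_to_array,
)

WM_EVALS = np.array([1.7e-3, 0.3e-3, 0.3e-3])


def _stick(axis, evals=WM_EVALS):
    return DiffusionTensor.from_evals(evals, axis)


def _crossing_voxel():
    return MultiTensorVoxel(
        [_stick([1, 0, 0]), _stick([0, 1, 0])], np.array([0.5, 0.5]), 1.0
    )


class TestPredictSignal:
    def test_b0_returns_s0(self):
        vox = MultiTensorVoxel([_stick([1, 0, 0])], np.array([1.0]), 123.0)
        assert predict_signal(vox, 0.0, [0, 0, 0]) == 123.0

    def test_isotropic_closed_form(self):
        d = 0.7e-3
        vox = MultiTensorVoxel(
            [DiffusionTensor(np.eye(3) * d)], np.array([1.0]), 2.0
        )
        for g in ([1, 0, 0], [0, 0, 1], np.array([1, 1, 1]) / np.sqrt(3)):
            np.testing.assert_allclose(
                predict_signal(vox, 1200.0, g), 2.0 * np.exp(-1200 * d), rtol=1e-12
            )

    def test_two_tensor_hand_sum(self):
        vox = _crossing_voxel()
        g = np.array([1.0, 0.0, 0.0])
        b = 1200.0
        # direct formula evaluation oracle
        expected = 0.5 * np.exp(-b * 1.7e-3) + 0.5 * np.exp(-b * 0.3e-3)
        np.testing.assert_allclose(predict_signal(vox, b, g), expected, rtol=1e-12)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            predict_signal(_crossing_voxel(), -1.0, [1, 0, 0])


class TestSingleTensorFit:
    def test_round_trip_61_directions(self, scheme):
        truth = _stick([0.6, 0.64, 0.48])
        vox = MultiTensorVoxel([truth], np.array([1.0]), 1.0)
        signals = predict_signals(vox, scheme)
        fitted, s0 = fit_single_tensor(signals, scheme)
        np.testing.assert_allclose(fitted.evals, truth.evals, rtol=1e-6)
        assert abs(abs(fitted.e1 @ truth.e1) - 1) < 1e-6
        assert abs(s0 - 1.0) < 1e-6

    def test_isotropic(self, scheme):
        d = 0.9e-3
        signals = np.exp(-scheme.bvals * d) * 5.0
        fitted, s0 = fit_single_tensor(signals, scheme)
        np.testing.assert_allclose(fitted.evals, d, rtol=1e-6)
        np.testing.assert_allclose(s0, 5.0, rtol=1e-6)

    def test_negative_signal_rejected(self, scheme):
        signals = np.ones(len(scheme))
        signals[20] = -0.5
        with pytest.raises(ValueError):
            fit_single_tensor(signals, scheme)

    def test_too_few_measurements(self):
        t = GradientTable(bvals=[0, 1200], bvecs=[[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            fit_single_tensor(np.ones(2), t)

    def test_all_zero_signals(self, scheme):
        with pytest.raises(ValueError):
            fit_single_tensor(np.zeros(len(scheme)), scheme)

    def test_simulate_fit_simulate_closes(self, scheme):
        truth = _stick([0, 1, 1])
        vox = MultiTensorVoxel([truth], np.array([1.0]), 1.0)
        signals = predict_signals(vox, scheme)
        fitted, s0 = fit_single_tensor(signals, scheme)
        refit = predict_signals(MultiTensorVoxel([fitted], np.array([1.0]), s0), scheme)
        np.testing.assert_allclose(refit, signals, rtol=1e-6)


class TestTwoTensorFit:
    def test_orthogonal_crossing_recovery(self, scheme):
        signals = predict_signals(_crossing_voxel(), scheme)
        fit = fit_two_tensor(signals, scheme)
        axes = sorted(
            (np.abs(t.e1) for t in fit.tensors), key=lambda a: -a[0]
        )
        assert np.degrees(np.arccos(np.clip(axes[0] @ [1, 0, 0], -1, 1))) < 2
        assert np.degrees(np.arccos(np.clip(axes[1] @ [0, 1, 0], -1, 1))) < 2
        np.testing.assert_allclose(fit.fractions, [0.5, 0.5], atol=0.05)

    def test_single_generator_degenerates(self, scheme):
        vox = MultiTensorVoxel([_stick([1, 0, 0])], np.array([1.0]), 1.0)
        signals = predict_signals(vox, scheme)
        single, s0 = fit_single_tensor(signals, scheme)
        rss1 = rss(signals, predict_signals(MultiTensorVoxel([single], np.array([1.0]), s0), scheme))
        fit = fit_two_tensor(signals, scheme)
        rss2 = rss(signals, predict_signals(fit, scheme))
        assert fit.fractions.max() >= 0.9 or rss2 >= rss1 - 1e-12

    def test_init_axis_swap_symmetry(self, scheme):
        signals = predict_signals(_crossing_voxel(), scheme)
        a = fit_two_tensor(signals, scheme, init_axes=(np.array([1.0, 0, 0]), np.array([0, 1.0, 0])))
        b = fit_two_tensor(signals, scheme, init_axes=(np.array([0, 1.0, 0]), np.array([1.0, 0, 0])))
        rss_a = rss(signals, predict_signals(a, scheme))
        rss_b = rss(signals, predict_signals(b, scheme))
        np.testing.assert_allclose(rss_a, rss_b, atol=1e-10)

    def test_rss_never_worse_than_single(self, scheme, rng):
        for _ in range(3):
            axis = rng.normal(size=3)
            vox = MultiTensorVoxel([_stick(axis)], np.array([1.0]), 1.0)
            signals = predict_signals(vox, scheme) + rng.normal(0, 0.01, len(scheme))
            signals = np.abs(signals)
            single, s0 = fit_single_tensor(signals, scheme)
            rss1 = rss(signals, predict_signals(MultiTensorVoxel([single], np.array([1.0]), s0), scheme))
            fit2 = fit_two_tensor(signals, scheme)
            rss2 = rss(signals, predict_signals(fit2, scheme))
            assert rss2 <= rss1 + 1e-12


class TestClassification:
    def test_single_tensor_voxel(self, scheme):
        vox = MultiTensorVoxel([_stick([1, 1, 0])], np.array([1.0]), 1.0)
        assert classify_fibre_count(predict_signals(vox, scheme), scheme) == 1

    def test_crossing_voxel(self, scheme):
        assert classify_fibre_count(predict_signals(_crossing_voxel(), scheme), scheme) == 2

    def test_crossing_f_statistic_oracle(self, scheme):
        # by-hand F from the two fits' RSS values must agree with the decision
        from scipy import stats

        signals = predict_signals(_crossing_voxel(), scheme)
        single, s0 = fit_single_tensor(signals, scheme)
        rss1 = rss(signals, predict_signals(MultiTensorVoxel([single], np.array([1.0]), s0), scheme))
        fit2 = fit_two_tensor(signals, scheme)
        rss2 = rss(signals, predict_signals(fit2, scheme))
        n = len(scheme)
        f = ((rss1 - rss2) / 7) / max(rss2 / (n - 14), 1e-300)
        assert stats.f.sf(f, 7, n - 14) < 0.05

    def test_isotropic_voxel(self, scheme):
        vox = MultiTensorVoxel([DiffusionTensor(np.eye(3) * 0.7e-3)], np.array([1.0]), 1.0)
        assert classify_fibre_count(predict_signals(vox, scheme), scheme) == 1


class TestScalars:
    def test_isotropic_fa_md(self):
        t = DiffusionTensor(np.eye(3) * 0.7e-3)
        assert compute_fa(t) == 0.0
        np.testing.assert_allclose(compute_md(t), 0.7e-3)

    def test_stick_extreme(self):
        assert compute_fa(np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_derived_value(self):
        # direct evaluation of the eigenvalue formula
        lam = np.array([2.0e-3, 0.2e-3, 0.2e-3])
        mean = lam.mean()
        expected = np.sqrt(1.5 * np.sum((lam - mean) ** 2) / np.sum(lam**2))
        assert expected == pytest.approx(0.891, abs=5e-4)
        assert compute_fa(lam) == pytest.approx(expected, rel=1e-12)

    def test_zero_tensor_fa_zero(self):
        assert compute_fa(DiffusionTensor(np.zeros((3, 3)))) == 0.0

    def test_fa_rotation_and_scale_invariance(self, rng):
        t = _stick([1, 2, 3])
        fa0 = compute_fa(t)
        for _ in range(5):
            r = Rotation.random(rng=rng).as_matrix()
            rotated = DiffusionTensor(r @ t.matrix @ r.T)
            assert compute_fa(rotated) == pytest.approx(fa0, abs=1e-12)
        scaled = DiffusionTensor(t.matrix * 7.5)
        assert compute_fa(scaled) == pytest.approx(fa0, abs=1e-12)

    def test_fraction_invariants(self):
        with pytest.raises(ValueError):
            MultiTensorVoxel([_stick([1, 0, 0])], np.array([0.9]), 1.0)


class TestFitTensorField:
    def test_noise_free_grid_fit(self, scheme):
        from acmap.io import BinaryMask
        from acmap.multitensor import fit_tensor_field

        truth = _stick([1, 0, 0])
        dwi = np.zeros((3, 1, 1, len(scheme)))
        mask = np.zeros((3, 1, 1), np.uint8)
        vox = MultiTensorVoxel([truth], np.array([1.0]), 1.0)
        for i in (0, 2):
            dwi[i, 0, 0] = predict_signals(vox, scheme)
            mask[i, 0, 0] = 1
        field = fit_tensor_field(
            dwi, scheme, BinaryMask(mask, np.eye(4)), np.eye(4)
        )
        np.testing.assert_array_equal(field.n_fibers[:, 0, 0], [1, 0, 1])
        fitted = DiffusionTensor(field.tensors[0, 0, 0, 0])
        np.testing.assert_allclose(fitted.evals, truth.evals, rtol=1e-5)


class TestTensorFieldSerialization:
    def test_round_trip(self, tube_phantom):
        field, _ = tube_phantom
        arr = tensor_field_to_array(field)
        back = tensor_field_from_array(arr, field.affine)
        np.testing.assert_allclose(back.tensors, field.tensors, atol=1e-9)
        np.testing.assert_array_equal(back.n_fibers, field.n_fibers)
        np.testing.assert_allclose(back.fractions, field.fractions, atol=1e-7)

    def test_voxel_accessors(self, tube_phantom):
        field, mask = tube_phantom
        i, j, k = mask.indices()[0]
        vox = field.get_voxel((i, j, k))
        assert vox.n_fibers == 1
        assert field.get_voxel((0, 0, 0)) is None
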