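"""Tensor model: scalar closed forms, fitting, interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tractprof as tp
from tractprof.phantom import default_gradient_table, synthesize_dwi, tensor_along_axis
from tractprof.tensor import (
    eigenvalues_descending,
    fa_from_eigenvalues,
    scalar_from_eigenvalues,
    tensor_elements,
)


@pytest.mark.parametrize(
    "ev, metric, expected",
    [
        ((1, 1, 1), "FA", 0.0),
        ((1, 1, 1), "MD", 1.0),
        ((1, 1, 1), "RD", 1.0),
        ((1, 1, 1), "AD", 1.0),
        ((1, 0, 0), "FA", 1.0),
        ((2, 1, 1), "FA", np.sqrt(1 / 6)),
        ((2, 1, 1), "MD", 4 / 3),
        ((2, 1, 1), "RD", 1.0),
        ((2, 1, 1), "AD", 2.0),
    ],
)
def test_scalar_closed_forms(ev, metric, expected):
    assert scalar_from_eigenvalues(np.array(ev, float), metric) == pytest.approx(expected, abs=1e-12)


def test_fa_of_zero_tensor_is_zero():
    assert fa_from_eigenvalues(np.zeros(3)) == 0.0


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.integers(min_value=0, max_value=10**9))
def test_fa_in_unit_interval_for_psd_tensors(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    D = A @ A.T  # PSD by construction
    fa = fa_from_eigenvalues(eigenvalues_descending(D))
    assert 0.0 <= fa <= 1.0 + 1e-12


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=10**9))
def test_md_equals_third_of_trace(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    D = (A + A.T) / 2
    md = scalar_from_eigenvalues(eigenvalues_descending(D), "MD")
    assert md == pytest.approx(np.trace(D) / 3, abs=1e-12)


def test_fa_rotation_invariance():
    rng = np.random.default_rng(3)
    D = np.diag([1.5e-3, 0.4e-3, 0.2e-3])
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    fa0 = fa_from_eigenvalues(eigenvalues_descending(D))
    fa1 = fa_from_eigenvalues(eigenvalues_descending(q @ D @ q.T))
    assert fa1 == pytest.approx(fa0, abs=1e-10)


class TestFit:
    def _uniform_volume(self, D, shape=(3, 3, 3)):
        gtab = default_gradient_table()
        fld = tp.TensorField(
            tensors=np.broadcast_to(D, shape + (3, 3)).copy(),
            affine=np.eye(4),
            mask=np.ones(shape, bool),
        )
        return synthesize_dwi(fld, gtab, noise_sd=0), fld

    def test_noiseless_round_trip(self):
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        vol, fld = self._uniform_volume(D)
        fit = tp.fit_tensor_volume(vol)
        assert np.abs(fit.tensors - fld.tensors).max() < 1e-10

    def test_isotropic_signal_gives_isotropic_tensor(self):
        d = 1.0e-3
        gtab = default_gradient_table()
        S = 100.0 * np.exp(-gtab.bvalues * d)
        vol = tp.DiffusionVolume(
            signal=np.broadcast_to(S, (2, 2, 2, S.size)).copy(), affine=np.eye(4), gradients=gtab
        )
        fit = tp.fit_tensor_volume(vol)
        assert np.allclose(fit.tensors, d * np.eye(3), atol=1e-12)
        fa = tp.scalar_map(fit, "FA")
        assert np.allclose(fa.values, 0.0, atol=1e-10)

    def test_robust_mode_rejects_corrupted_direction(self):
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        vol, fld = self._uniform_volume(D)
        sig = vol.signal.copy()
        sig[..., 5] *= 5.0  # one corrupted gradient direction
        bad = tp.DiffusionVolume(signal=sig, affine=np.eye(4), gradients=vol.gradients)
        err_robust = np.abs(tp.fit_tensor_volume(bad, robust=True).tensors - fld.tensors).max()
        err_plain = np.abs(tp.fit_tensor_volume(bad, robust=False).tensors - fld.tensors).max()
        assert err_robust < 1e-3
        assert err_plain > err_robust

    def test_fit_simulate_fit_idempotent(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3)) * 1e-3
        D = (A @ A.T) / 3 + 0.3e-3 * np.eye(3)
        vol, _ = self._uniform_volume(D)
        fit1 = tp.fit_tensor_volume(vol)
        vol2 = synthesize_dwi(fit1, vol.gradients, noise_sd=0)
        fit2 = tp.fit_tensor_volume(vol2)
        assert np.abs(fit2.tensors - fit1.tensors).max() < 1e-10

    def test_too_few_directions_raises(self):
        gtab = tp.GradientTable(
            directions=np.vstack([np.zeros(3), np.eye(3), np.eye(3)]),
            bvalues=np.array([0.0] + [900.0] * 6),
        )
        with pytest.raises(ValueError, match="distinct"):
            gtab.validate_for_fit()

    def test_nonpositive_signals_masked_with_warning(self):
        D = np.diag([1.0e-3, 1.0e-3, 1.0e-3])
        vol, _ = self._uniform_volume(D)
        sig = vol.signal.copy()
        sig[0, 0, 0, 3] = 0.0
        bad = tp.DiffusionVolume(signal=sig, affine=np.eye(4), gradients=vol.gradients)
        with pytest.warns(UserWarning, match="nonpositive"):
            fit = tp.fit_tensor_volume(bad)
        assert not fit.mask[0, 0, 0]
        assert fit.mask.sum() == fit.mask.size - 1


class TestInterpolation:
    def _field_from_tensors(self, tensors, voxel=1.0):
        aff = np.diag([voxel, voxel, voxel, 1.0])
        return tp.TensorField(tensors=tensors, affine=aff, mask=np.ones(tensors.shape[:3], bool))

    def test_tensor_at_voxel_center_identity(self):
        rng = np.random.default_rng(1)
        T = rng.normal(size=(4, 4, 4, 3, 3))
        T = (T + np.swapaxes(T, -1, -2)) / 2
        fld = self._field_from_tensors(T)
        got = tp.interpolate_tensor(fld, np.array([2.0, 1.0, 3.0]))
        assert np.allclose(got, T[2, 1, 3], atol=1e-12)

    def test_tensor_midpoint_is_average(self):
        T = np.zeros((3, 3, 3, 3, 3))
        A = np.diag([1.0, 2.0, 3.0])
        B = np.diag([3.0, 2.0, 1.0])
        T[1, 1, 1] = A
        T[2, 1, 1] = B
        fld = self._field_from_tensors(T)
        got = tp.interpolate_tensor(fld, np.array([1.5, 1.0, 1.0]))
        assert np.allclose(got, (A + B) / 2, atol=1e-12)
        assert np.allclose(got, got.T)

    def test_constant_field_constant_everywhere(self):
        D = np.diag([1.0, 1.0, 2.0])
        fld = self._field_from_tensors(np.broadcast_to(D, (4, 4, 4, 3, 3)).copy())
        pts = np.random.default_rng(0).uniform(0.2, 2.8, size=(20, 3))
        got = tp.interpolate_tensor(fld, pts)
        assert np.allclose(got, D, atol=1e-12)

    def test_outside_bounds_raises(self):
        fld = self._field_from_tensors(np.zeros((3, 3, 3, 3, 3)))
        with pytest.raises(ValueError, match="outside"):
            tp.interpolate_tensor(fld, np.array([5.0, 1.0, 1.0]))

    def test_scalar_constant_map(self):
        sm = tp.ScalarMap(values=np.full((5, 5, 5), 3.25), metric="FA", affine=np.eye(4))
        pts = np.random.default_rng(0).uniform(0.5, 3.5, size=(10, 3))
        assert np.allclose(tp.interpolate_scalar(sm, pts), 3.25, atol=1e-10)

    def test_scalar_linear_map_reproduced(self):
        x = np.arange(10, dtype=float)
        vals = np.broadcast_to(2.0 * x[:, None, None] + 1.0, (10, 6, 6)).copy()
        sm = tp.ScalarMap(values=vals, metric="FA", affine=np.eye(4))
        pts = np.column_stack([np.linspace(1.2, 7.8, 15), np.full(15, 2.5), np.full(15, 2.5)])
        assert np.allclose(tp.interpolate_scalar(sm, pts), 2.0 * pts[:, 0] + 1.0, atol=1e-9)

    def test_scalar_sinusoid_accuracy(self):
        # 2 mm voxels; smooth sinusoid sampled off-grid matches analytic within 1e-3
        n = 30
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        xs = 2.0 * np.arange(n)
        f = lambda x: np.sin(2 * np.pi * x / 40.0)
        vals = np.broadcast_to(f(xs)[:, None, None], (n, 8, 8)).copy()
        sm = tp.ScalarMap(values=vals, metric="FA", affine=aff)
        px = np.linspace(6.0, 50.0, 40)
        pts = np.column_stack([px, np.full(40, 7.0), np.full(40, 7.0)])
        assert np.abs(tp.interpolate_scalar(sm, pts) - f(px)).max() < 1e-3

    def test_scalar_outside_bounds_is_nan(self):
        sm = tp.ScalarMap(values=np.ones((4, 4, 4)), metric="FA", affine=np.eye(4))
        out = tp.interpolate_scalar(sm, np.array([[10.0, 1.0, 1.0], [1.0, 1.0, 1.0]]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(1.0)


def test_tensor_elements_round_trip():
    from tractprof.tensor import _tensor_from_elements

    rng = np.random.default_rng(2)
    T = rng.normal(size=(5, 3, 3))
    T = (T + np.swapaxes(T, -1, -2)) / 2
    assert np.allclose(_tensor_from_elements(tensor_elements(T)), T)
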