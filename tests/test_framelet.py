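"""Tensor framelet transform: tight-frame identity, norm, shrinkage."""

import numpy as np
import pytest

from tfct.errors import ValidationError
from tfct.framelet import (
    FrameletCoeffs,
    RegWeights,
    base_masks,
    dilated_mask,
    tf_adjoint,
    tf_forward,
    tf_norm,
    tf_shrink,
)

SQRT3 = np.sqrt(3.0)


def _circ_apply(mask, n):
    """Dense circulant matrix of the correlation used by the transform."""
    m = np.zeros((n, n))
    d = (len(mask) - 1) // 2
    for i in range(n):
        m[i, (i - d) % n] += mask[0]
        m[i, i] += mask[len(mask) // 2]
        m[i, (i + d) % n] += mask[-1]
    return m


class TestMasks:
    def test_base_mask_values(self):
        w = base_masks()
        assert np.allclose(w[0], [0.25, 0.5, 0.25])
        assert np.allclose(w[1], np.array([1, 0, -1]) * np.sqrt(2) / 4)
        assert np.allclose(w[2], [-0.25, 0.5, -0.25])

    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_tap_sums_and_dilution(self, level):
        # lowpass taps sum to 1; band taps sum to 0; zeros inserted between taps
        assert dilated_mask(0, level).sum() == pytest.approx(1.0)
        assert dilated_mask(1, level).sum() == pytest.approx(0.0)
        assert dilated_mask(2, level).sum() == pytest.approx(0.0, abs=1e-15)
        assert len(dilated_mask(0, level)) == 2 ** level + 1

    @pytest.mark.parametrize("level", [1, 2, 3])
    def test_tight_frame_identity_per_level(self, level):
        # sum_j omega_j^T omega_j acts as the identity under circular boundary
        n = 16
        total = np.zeros((n, n))
        for j in range(3):
            m = _circ_apply(dilated_mask(j, level), n)
            total += m.T @ m
        assert np.max(np.abs(total - np.eye(n))) < 1e-12


class TestTransform:
    @pytest.mark.parametrize("levels", [1, 2, 3])
    def test_perfect_reconstruction_anisotropic(self, rng, levels):
        x = rng.normal(size=(16, 12, 8))
        c = tf_forward(x, levels)
        assert np.max(np.abs(tf_adjoint(c) - x)) < 1e-10

    def test_constant_volume_bands_vanish(self):
        x = np.full((8, 8, 8), 3.7)
        c = tf_forward(x, 2)
        for lev in c.bands:
            for j in (1, 2):
                assert np.max(np.abs(lev[j])) < 1e-14
        # per-axis lowpass chains preserve the constant (up to the 1/sqrt3 weight)
        assert np.allclose(c.lowpass, 3.7 / SQRT3)

    def test_ramp_band_stencil_value(self):
        # along-x ramp: level-1 j=1 x-component = (1/sqrt3)(sqrt2/4)(x_{i-1}-x_{i+1})
        n = 16
        x = np.tile(np.arange(n, dtype=float)[:, None, None], (1, 4, 4))
        c = tf_forward(x, 1)
        interior = c.bands[0][1][0][1:-1]  # x-axis component, interior voxels
        expected = -(1 / SQRT3) * (np.sqrt(2) / 2)
        assert np.allclose(interior, expected)

    def test_adjoint_identity_dot_product(self, rng):
        x = rng.normal(size=(12, 10, 8))
        c = tf_forward(x, 2)
        d = FrameletCoeffs(
            [{j: rng.normal(size=(3,) + x.shape) for j in (1, 2)} for _ in range(2)],
            rng.normal(size=(3,) + x.shape))
        lhs = c.dot(d)
        rhs = float(np.sum(x * tf_adjoint(d)))
        assert abs(lhs - rhs) / (c.norm2() * d.norm2()) < 1e-10

    def test_parseval(self, rng):
        x = rng.normal(size=(16, 16, 16))
        for levels in (1, 2, 3):
            c = tf_forward(x, levels)
            assert c.norm2() == pytest.approx(np.linalg.norm(x), rel=1e-10)

    def test_zero_coeffs_give_zero_volume(self):
        c = tf_forward(np.zeros((8, 8, 8)), 2)
        assert np.all(tf_adjoint(FrameletCoeffs.zeros_like(c)) == 0)

    def test_m0_band_only_for_unilevel(self, rng):
        x = rng.normal(size=(8, 8, 8))
        c1 = tf_forward(x, 1)
        # for L=1 the lowpass IS the M0 band: omega_0 along each axis / sqrt3
        from tfct.framelet import _conv_axis
        for a in range(3):
            assert np.allclose(c1.m0[a], _conv_axis(x, 0, 1, axis=a) / SQRT3)
        with pytest.raises(ValidationError):
            _ = tf_forward(x, 2).m0

    def test_level_too_deep_rejected(self):
        with pytest.raises(ValidationError):
            tf_forward(np.zeros((16, 16, 4)), 4)  # 2^(L-1)=8 >= 4


class TestNorm:
    def test_zero_volume(self):
        c = tf_forward(np.zeros((8, 8, 8)), 1)
        assert tf_norm(c, RegWeights.uniform(1.0, 1)) == 0.0

    def test_three_four_five_magnitude(self):
        c = tf_forward(np.zeros((6, 6, 6)), 1)
        c.bands[0][1][0, 2, 3, 4] = 3.0
        c.bands[0][1][1, 2, 3, 4] = 4.0
        w = RegWeights(np.array([[1.0, 0.0]]))
        assert tf_norm(c, w) == pytest.approx(5.0)

    def test_homogeneous_degree_one(self, rng):
        x = rng.normal(size=(8, 8, 8))
        w = RegWeights.uniform(0.7, 2, lowpass=0.3)
        c1 = tf_norm(tf_forward(x, 2), w)
        c2 = tf_norm(tf_forward(2.5 * x, 2), w)
        assert c2 == pytest.approx(2.5 * c1, rel=1e-12)

    def test_tv_configuration_matches_isotropic_tv(self, rng):
        # lambda_0=0, lambda_1=1, lambda_2=0, L=1 equals the central-difference
        # isotropic TV times (1/sqrt3)(sqrt2/2)
        x = rng.normal(size=(10, 12, 9))
        val = tf_norm(tf_forward(x, 1), RegWeights.tv(1.0))
        grads = [(np.roll(x, 1, a) - np.roll(x, -1, a)) / 2.0 for a in range(3)]
        tv = float(np.sqrt(sum(g ** 2 for g in grads)).sum())
        const = (1 / SQRT3) * (np.sqrt(2) / 2)
        assert val == pytest.approx(const * tv, rel=1e-10)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValidationError):
            RegWeights(np.array([[-0.1, 0.0]]))


class TestShrink:
    def _coeffs(self, shape=(6, 6, 6)):
        return tf_forward(np.zeros(shape), 1)

    def test_closed_form_three_four_zero(self):
        c = self._coeffs()
        c.bands[0][1][:, 1, 1, 1] = [3.0, 4.0, 0.0]
        out = tf_shrink(c, RegWeights(np.array([[2.5, 0.0]])), mu=1.0)
        assert np.allclose(out.bands[0][1][:, 1, 1, 1], [1.5, 2.0, 0.0])

    def test_dead_zone_gives_zero(self):
        c = self._coeffs()
        c.bands[0][1][:, 0, 0, 0] = [0.3, 0.4, 0.0]  # magnitude 0.5 <= t
        out = tf_shrink(c, RegWeights(np.array([[0.5, 0.0]])), mu=1.0)
        assert np.all(out.bands[0][1][:, 0, 0, 0] == 0.0)

    def test_zero_threshold_is_identity(self, rng):
        x = rng.normal(size=(8, 8, 8))
        c = tf_forward(x, 2)
        out = tf_shrink(c, RegWeights.uniform(0.0, 2), mu=1.0)
        for a, b in zip(out.arrays(), c.arrays()):
            assert np.array_equal(a, b)
        # composed with the adjoint it returns x exactly
        assert np.max(np.abs(tf_adjoint(out) - x)) < 1e-10

    def test_nonexpansive(self, rng):
        w = RegWeights.uniform(0.8, 2, lowpass=0.2)
        for _ in range(10):
            a = tf_forward(rng.normal(size=(8, 8, 8)), 2)
            b = tf_forward(rng.normal(size=(8, 8, 8)), 2)
            sa = tf_shrink(a, w, mu=1.3)
            sb = tf_shrink(b, w, mu=1.3)
            assert (sa - sb).norm2() <= (a - b).norm2() + 1e-12

    def test_mu_must_be_positive(self):
        with pytest.raises(ValidationError):
            tf_shrink(self._coeffs(), RegWeights.uniform(1.0, 1), mu=0.0)

    def test_shrink_is_prox_of_weighted_norm(self, rng):
        # output must beat random perturbations on 0.5*mu*||d-c||^2 + lam*||d||_1
        c = tf_forward(rng.normal(size=(6, 6, 6)), 1)
        w = RegWeights.uniform(0.4, 1)
        mu = 2.0
        d = tf_shrink(c, w, mu)

        def objective(dd):
            return 0.5 * mu * (dd - c).norm2() ** 2 + tf_norm(dd, w)

        base = objective(d)
        for scale in (1e-3, 1e-2):
            pert = FrameletCoeffs(
                [{j: d.bands[0][j] + scale * rng.normal(size=d.bands[0][j].shape)
                  for j in (1, 2)}], d.lowpass.copy())
            assert objective(pert) >= base - 1e-12
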