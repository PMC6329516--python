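"""Multilevel 3D tensor framelet transform W, adjoint W^T, norm and shrinkage.

The transform applies the 1D piecewise-linear tight frame with refinement
masks

    omega_0 = 1/4 [1, 2, 1]        (average / lowpass)
    omega_1 = sqrt(2)/4 [1, 0, -1] (first difference)
    omega_2 = 1/4 [-1, 2, -1]      (second difference)

along each of the three axis unfoldings of the volume, combined with weight
1/sqrt(3).  Level ``l`` uses the "diluted" (a-trous) masks with 2^(l-1) - 1
zeros inserted between taps, and each axis carries its own lowpass chain
x_a^l = omega_0^l * x_a^(l-1).  Convolutions are circular (periodic), so the
tight-frame identity W^T W = I holds *exactly* (to rounding): per axis and
level, sum_j omega_j^T omega_j = I, the per-axis cascades telescope, and the
1/3 from the axis weight averages the three identities.

Coefficients are undecimated: every band sub-volume has the input's shape.
The lowpass, like the bands, keeps its three per-axis components (for L = 1
it *is* the M_0 band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "base_masks",
    "dilated_mask",
    "RegWeights",
    "FrameletCoeffs",
    "tf_forward",
    "tf_adjoint",
    "tf_norm",
    "tf_shrink",
]

_SQRT3 = np.sqrt(3.0)


def base_masks() -> dict[int, np.ndarray]:
    """The three refinement masks, taps at offsets (-1, 0, +1)."""
    return {
        0: np.array([1.0, 2.0, 1.0]) / 4.0,
        1: np.array([1.0, 0.0, -1.0]) * (np.sqrt(2.0) / 4.0),
        2: np.array([-1.0, 2.0, -1.0]) / 4.0,
    }


def dilated_mask(j: int, level: int) -> np.ndarray:
    """Level-``level`` mask: 2^(level-1) - 1 zeros inserted between taps."""
    if level < 1:
        raise ValidationError("level must be >= 1")
    taps = base_masks()[j]
    d = 2 ** (level - 1)
    out = np.zeros(2 * d + 1)
    out[[0, d, 2 * d]] = taps
    return out


def _conv_axis(x: np.ndarray, j: int, level: int, axis: int) -> np.ndarray:
    """Circular correlation y_i = sum_m w_m x_(i + m*d), taps m in {-1,0,1}."""
    w = base_masks()[j]
    d = 2 ** (level - 1)
    return (w[0] * np.roll(x, d, axis=axis)
            + w[1] * x
            + w[2] * np.roll(x, -d, axis=axis))


def _conv_axis_adjoint(x: np.ndarray, j: int, level: int, axis: int) -> np.ndarray:
    """Transpose of :func:`_conv_axis` (rolls reversed)."""
    w = base_masks()[j]
    d = 2 ** (level - 1)
    return (w[0] * np.roll(x, -d, axis=axis)
            + w[1] * x
            + w[2] * np.roll(x, d, axis=axis))


@dataclass
class RegWeights:
    """Per-(level, band) regularization weights lambda_{l,j} plus lowpass weight.

    ``band`` has shape (L, 2): column 0 is j=1 (first difference), column 1 is
    j=2 (second difference).  ``lowpass`` is lambda_{L,0} (default 0: the
    lowpass l1 penalty is unusual and off unless requested).
    """

    band: np.ndarray
    lowpass: float = 0.0

    def __post_init__(self) -> None:
        self.band = np.atleast_2d(np.asarray(self.band, dtype=float))
        if self.band.ndim != 2 or self.band.shape[1] != 2:
            raise ValidationError("band weights must have shape (L, 2)")
        if np.any(self.band < 0) or self.lowpass < 0:
            raise ValidationError("regularization weights must be non-negative")

    @classmethod
    def uniform(cls, lam: float, levels: int, lowpass: float = 0.0) -> "RegWeights":
        """Single scalar lambda broadcast to all (l, j) bands."""
        return cls(np.full((levels, 2), float(lam)), lowpass)

    @classmethod
    def tv(cls, lam: float) -> "RegWeights":
        """The isotropic-TV configuration: L = 1, lambda_1 = lam, others 0."""
        return cls(np.array([[float(lam), 0.0]]), 0.0)

    @property
    def levels(self) -> int:
        return self.band.shape[0]


@dataclass
class FrameletCoeffs:
    """Transform-domain object Wx.

    ``bands[l][j]`` (l = 0..L-1 for levels 1..L, j in {1, 2}) is an array of
    shape (3, nx, ny, nz): the x/y/z axis components, each scaled by 1/sqrt(3).
    ``lowpass`` has the same (3, ...) layout and holds the end of each axis's
    lowpass chain.  For L = 1 this equals the uni-level M_0 band.
    """

    bands: list[dict[int, np.ndarray]]
    lowpass: np.ndarray
    shape: tuple[int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.shape is None:
            self.shape = tuple(self.lowpass.shape[1:])
        self.validate()

    def validate(self) -> None:
        want = (3,) + tuple(self.shape)
        if self.lowpass.shape != want:
            raise ValidationError("lowpass components have inconsistent shape")
        for lev in self.bands:
            if set(lev.keys()) != {1, 2}:
                raise ValidationError("each level must carry bands j = 1 and j = 2")
            for arr in lev.values():
                if arr.shape != want:
                    raise ValidationError("band sub-volume shape mismatch")

    @property
    def levels(self) -> int:
        return len(self.bands)

    @property
    def m0(self) -> np.ndarray:
        """Uni-level M_0 band (only meaningful for L = 1)."""
        if self.levels != 1:
            raise ValidationError("the M_0 band is exposed only for L = 1")
        return self.lowpass

    def arrays(self):
        """All sub-volume arrays in a fixed order (bands by level/j, lowpass)."""
        for lev in self.bands:
            for j in (1, 2):
                yield lev[j]
        yield self.lowpass

    # -- linear-space arithmetic (needed by the ADMM auxiliaries) ---------
    def _zip(self, other: "FrameletCoeffs", op) -> "FrameletCoeffs":
        if other.levels != self.levels or other.shape != self.shape:
            raise ValidationError("framelet coefficient structures do not match")
        bands = [{j: op(a[j], b[j]) for j in (1, 2)}
                 for a, b in zip(self.bands, other.bands)]
        return FrameletCoeffs(bands, op(self.lowpass, other.lowpass), self.shape)

    def __add__(self, other: "FrameletCoeffs") -> "FrameletCoeffs":
        return self._zip(other, np.add)

    def __sub__(self, other: "FrameletCoeffs") -> "FrameletCoeffs":
        return self._zip(other, np.subtract)

    def copy(self) -> "FrameletCoeffs":
        return FrameletCoeffs([{j: lev[j].copy() for j in (1, 2)} for lev in self.bands],
                              self.lowpass.copy(), self.shape)

    @classmethod
    def zeros_like(cls, other: "FrameletCoeffs") -> "FrameletCoeffs":
        bands = [{j: np.zeros_like(lev[j]) for j in (1, 2)} for lev in other.bands]
        return cls(bands, np.zeros_like(other.lowpass), other.shape)

    def dot(self, other: "FrameletCoeffs") -> float:
        return float(sum(np.vdot(a, b).real
                         for a, b in zip(self.arrays(), other.arrays())))

    def norm2(self) -> float:
        return float(np.sqrt(sum(np.sum(a * a) for a in self.arrays())))


def tf_forward(volume: np.ndarray, levels: int = 1) -> FrameletCoeffs:
    """Tensor framelet analysis Wx with ``levels`` decomposition levels."""
    x = np.asarray(volume, dtype=np.float64)
    if x.ndim != 3:
        raise ValidationError("tf_forward expects a 3D volume")
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    if 2 ** (levels - 1) >= min(x.shape):
        raise ValidationError(
            f"levels={levels} too deep for grid {x.shape}: 2^(L-1) must be "
            "smaller than the smallest dimension")
    low = np.stack([x, x, x])  # per-axis lowpass chains
    bands: list[dict[int, np.ndarray]] = []
    for lev in range(1, levels + 1):
        level_bands: dict[int, np.ndarray] = {}
        for j in (1, 2):
            level_bands[j] = np.stack(
                [_conv_axis(low[a], j, lev, axis=a) for a in range(3)]) / _SQRT3
        bands.append(level_bands)
        low = np.stack([_conv_axis(low[a], 0, lev, axis=a) for a in range(3)])
    return FrameletCoeffs(bands, low / _SQRT3, x.shape)


def tf_adjoint(coeffs: FrameletCoeffs) -> np.ndarray:
    """Synthesis W^T c: exact transpose of :func:`tf_forward`.

    Because W is a tight frame, ``tf_adjoint(tf_forward(x)) == x``.
    """
    coeffs.validate()
    levels = coeffs.levels
    # Reverse the per-axis lowpass cascades, folding in band adjoints per level.
    acc = coeffs.lowpass / _SQRT3  # (3, ...) per-axis accumulators
    acc = np.stack([_conv_axis_adjoint(acc[a], 0, levels, axis=a) for a in range(3)])
    for lev in range(levels, 0, -1):
        for j in (1, 2):
            band = coeffs.bands[lev - 1][j] / _SQRT3
            acc = acc + np.stack(
                [_conv_axis_adjoint(band[a], j, lev, axis=a) for a in range(3)])
        if lev > 1:
            acc = np.stack([_conv_axis_adjoint(acc[a], 0, lev - 1, axis=a)
                            for a in range(3)])
    return acc.sum(axis=0)


def _check_weights(coeffs: FrameletCoeffs, weights: RegWeights) -> None:
    if weights.levels != coeffs.levels:
        raise ValidationError(
            f"weights cover {weights.levels} levels but coefficients have {coeffs.levels}")


def tf_norm(coeffs: FrameletCoeffs, weights: RegWeights) -> float:
    """Weighted isotropic TF norm lambda * ||Wx||_1.

    Per voxel and band the three axis components are combined isotropically,
    sqrt(c_x^2 + c_y^2 + c_z^2); the lowpass term (weight lambda_{L,0}) is a
    plain component-wise l1.
    """
    _check_weights(coeffs, weights)
    total = 0.0
    for lev_idx, lev in enumerate(coeffs.bands):
        for j in (1, 2):
            lam = weights.band[lev_idx, j - 1]
            if lam > 0:
                mag = np.sqrt(np.sum(lev[j] ** 2, axis=0))
                total += lam * float(mag.sum())
    if weights.lowpass > 0:
        total += weights.lowpass * float(np.abs(coeffs.lowpass).sum())
    return total


def _iso_shrink(c: np.ndarray, t: float) -> np.ndarray:
    """Isotropic (vector) soft-threshold of a (3, ...) band by t."""
    if t <= 0:
        return c.copy()
    mag = np.sqrt(np.sum(c * c, axis=0))
    scale = np.zeros_like(mag)
    nz = mag > 0
    scale[nz] = np.maximum(mag[nz] - t, 0.0) / mag[nz]
    return c * scale


def tf_shrink(coeffs: FrameletCoeffs, thresholds: RegWeights, mu: float) -> FrameletCoeffs:
    """Isotropic shrinkage: the exact proximal map of (1/mu) * tf_norm.

    Each band voxel's 3-component magnitude m is soft-thresholded by
    t = lambda_{l,j} / mu preserving direction: c * max(m - t, 0) / m.
    The lowpass is soft-thresholded scalar-wise with t = lambda_{L,0} / mu.
    """
    if mu <= 0:
        raise ValidationError("mu must be > 0")
    _check_weights(coeffs, thresholds)
    bands = []
    for lev_idx, lev in enumerate(coeffs.bands):
        bands.append({j: _iso_shrink(lev[j], thresholds.band[lev_idx, j - 1] / mu)
                      for j in (1, 2)})
    t0 = thresholds.lowpass / mu
    low = np.sign(coeffs.lowpass) * np.maximum(np.abs(coeffs.lowpass) - t0, 0.0) \
        if t0 > 0 else coeffs.lowpass.copy()
    return FrameletCoeffs(bands, low, coeffs.shape)
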