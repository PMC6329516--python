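"""Iterative TF/TV reconstruction by ADMM (split Bregman) and an FDK baseline.

The regularized problem

    min_x  1/2 ||A x - y||_2^2 + lambda ||W x||_1

is split with auxiliaries d ~ Wx and multiplier v into three steps per outer
iteration:

    Step 1 (x-update):  (A^T A + mu I) x = A^T y + mu W^T (d - v),
                        solved by warm-started conjugate gradients; the
                        identity W^T W = I collapses the framelet term to
                        mu I, which is the efficiency advantage of the tight
                        frame over TV here.
    Step 2 (d-update):  d = shrink(W x + v, lambda / mu)   (isotropic).
    Step 3 (v-update):  v = v + W x - d.

TV reconstruction is the L = 1, (lambda_1 > 0, lambda_2 = 0) weight
configuration of the same solver.  The FDK baseline is a simplified helical
Feldkamp: cosine weighting, row-wise ramp filtering with a smooth rolloff,
distance-weighted backprojection with per-voxel angular-redundancy
normalization over the views whose detector z-window covers the voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .errors import SolverError, ValidationError
from .framelet import FrameletCoeffs, RegWeights, tf_adjoint, tf_forward, tf_norm, tf_shrink
from .geometry import Sinogram, view_arrays
from .grid import Volume, VolumeGrid
from .projector import back_project, forward_project

__all__ = [
    "ADMMConfig",
    "ReconResult",
    "cg_solve",
    "admm_reconstruct",
    "tv_reconstruct",
    "fdk_reconstruct",
]


# ---------------------------------------------------------------------------
# Conjugate gradients for the x-update normal operator
# ---------------------------------------------------------------------------

@dataclass
class CGInfo:
    iterations: int
    converged: bool
    relative_residual: float
    residual_history: list[float] = field(default_factory=list)


def cg_solve(apply_normal_op, rhs: np.ndarray, *, x0: np.ndarray | None = None,
             max_iter: int = 20, tol: float = 1e-6) -> tuple[np.ndarray, CGInfo]:
    """Conjugate gradients for the SPD system ``apply_normal_op(x) = rhs``.

    ``apply_normal_op`` maps a volume-shaped array to (A^T A + mu I) x.
    Returns the iterate and a :class:`CGInfo` stating whether the relative
    residual ||op(x) - rhs|| / ||rhs|| reached ``tol`` or the iteration
    budget was spent.
    """
    rhs = np.asarray(rhs, dtype=np.float64)
    if not np.all(np.isfinite(rhs)):
        raise ValidationError("cg_solve: rhs contains non-finite values")
    if max_iter < 1 or tol <= 0:
        raise ValidationError("cg_solve: max_iter >= 1 and tol > 0 required")
    bnorm = float(np.linalg.norm(rhs))
    if bnorm == 0.0:
        return np.zeros_like(rhs), CGInfo(0, True, 0.0, [0.0])
    x = np.zeros_like(rhs) if x0 is None else np.array(x0, dtype=np.float64)
    r = rhs - apply_normal_op(x)
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    history = [np.sqrt(rs) / bnorm]
    converged = history[-1] <= tol
    it = 0
    while not converged and it < max_iter:
        ap = apply_normal_op(p)
        denom = float(np.vdot(p, ap).real)
        if denom <= 0:
            raise SolverError("cg_solve: operator is not positive definite")
        alpha = rs / denom
        x += alpha * p
        r -= alpha * ap
        rs_new = float(np.vdot(r, r).real)
        it += 1
        history.append(np.sqrt(rs_new) / bnorm)
        converged = history[-1] <= tol
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, CGInfo(it, converged, history[-1], history)


# ---------------------------------------------------------------------------
# ADMM / split Bregman
# ---------------------------------------------------------------------------

@dataclass
class ADMMConfig:
    """Solver parameters for the TF-regularized reconstruction.

    The sinogram is internally rescaled so max|y| = 1 before solving (the
    result is scaled back), so ``mu`` and the weights are quoted on
    normalized data.  ``weights`` may be a :class:`RegWeights` or a scalar
    lambda broadcast to all (l, j) bands with zero lowpass weight.
    """

    weights: RegWeights | float = 1e-3
    mu: float = 1.0
    levels: int = 2
    outer_iterations: int = 30
    cg_iterations: int = 20
    cg_tolerance: float = 1e-6
    init: str = "zero"  # "zero" | "fdk"
    seed: int = 0
    early_stop_tol: float | None = None  # relative x-change; off by default
    log_stream: object = None  # optional text stream for per-iteration lines

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValidationError("mu must be > 0")
        if self.outer_iterations < 1 or self.cg_iterations < 1:
            raise ValidationError("iteration counts must be >= 1")
        if self.cg_tolerance <= 0:
            raise ValidationError("cg_tolerance must be > 0")
        if self.levels < 1:
            raise ValidationError("levels must be >= 1")
        if self.init not in ("zero", "fdk"):
            raise ValidationError("init must be 'zero' or 'fdk'")

    def resolved_weights(self) -> RegWeights:
        if isinstance(self.weights, RegWeights):
            if self.weights.levels != self.levels:
                raise ValidationError("weights levels do not match config levels")
            return self.weights
        return RegWeights.uniform(float(self.weights), self.levels)


@dataclass
class ReconResult:
    volume: Volume
    objective_trace: list[float]
    fidelity_trace: list[float]
    iterations_run: int

    def __post_init__(self) -> None:
        if not (len(self.objective_trace) == len(self.fidelity_trace) == self.iterations_run):
            raise ValidationError("trace lengths must equal iterations_run")
        if not all(np.isfinite(self.objective_trace)) or not all(np.isfinite(self.fidelity_trace)):
            raise ValidationError("traces contain non-finite values")


def admm_reconstruct(sino: Sinogram, grid: VolumeGrid, config: ADMMConfig) -> ReconResult:
    """TF-regularized reconstruction of ``sino`` onto ``grid`` by ADMM."""
    geom = sino.geometry
    weights = config.resolved_weights()
    levels = config.levels
    mu = config.mu

    scale = float(np.max(np.abs(sino.data)))
    if scale == 0.0:
        scale = 1.0
    y = Sinogram(sino.data / scale, geom)

    def A(x: np.ndarray) -> np.ndarray:
        return forward_project(Volume(x, grid), geom).data

    def At(s: np.ndarray) -> np.ndarray:
        return back_project(Sinogram(s, geom), grid).data

    def normal_op(x: np.ndarray) -> np.ndarray:
        return At(A(x)) + mu * x

    if config.init == "fdk":
        x = fdk_reconstruct(y, grid).data
    else:
        x = np.zeros(grid.shape)
    aty = At(y.data)
    wx = tf_forward(x, levels)
    d = wx.copy()
    v = FrameletCoeffs.zeros_like(wx)

    obj_trace: list[float] = []
    fid_trace: list[float] = []
    for it in range(1, config.outer_iterations + 1):
        rhs = aty + mu * tf_adjoint(d - v)
        x, _ = cg_solve(normal_op, rhs, x0=x,
                        max_iter=config.cg_iterations, tol=config.cg_tolerance)
        if not np.all(np.isfinite(x)):
            raise SolverError(f"ADMM diverged: non-finite iterate at outer iteration {it}")
        x_prev_norm = float(np.linalg.norm(x))
        wx = tf_forward(x, levels)
        d = tf_shrink(wx + v, weights, mu)
        v = v + wx - d

        residual = A(x) - y.data
        fid = 0.5 * float(np.sum(residual * residual))
        obj = fid + tf_norm(wx, weights)
        fid_trace.append(fid)
        obj_trace.append(obj)
        if config.log_stream is not None:
            print(f"iter={it} fidelity={fid:.6e} tf_norm={obj - fid:.6e} "
                  f"objective={obj:.6e}", file=config.log_stream)
        if config.early_stop_tol is not None and it > 1:
            # relative change uses the CG update just applied
            dx = float(np.linalg.norm(x - _last_x)) / max(x_prev_norm, 1e-30)
            if dx < config.early_stop_tol:
                break
        _last_x = x.copy()

    return ReconResult(Volume(x * scale, grid), obj_trace, fid_trace, len(obj_trace))


def tv_reconstruct(sino: Sinogram, grid: VolumeGrid, config: ADMMConfig) -> ReconResult:
    """Isotropic-TV reconstruction: the L=1, (lambda_1>0, lambda_2=0) TF config."""
    if isinstance(config.weights, RegWeights):
        if config.weights.levels != 1:
            raise ValidationError("tv_reconstruct requires single-level weights")
        lam = float(config.weights.band[0, 0])
    else:
        lam = float(config.weights)
    cfg = replace(config, weights=RegWeights.tv(lam), levels=1)
    return admm_reconstruct(sino, grid, cfg)


# ---------------------------------------------------------------------------
# Simplified helical FDK baseline
# ---------------------------------------------------------------------------

def _ramp_kernel(n: int, du: float) -> np.ndarray:
    """Band-limited spatial ramp kernel h (Ram-Lak), wrap-around layout."""
    h = np.zeros(n)
    h[0] = 1.0 / (4.0 * du * du)
    k = np.arange(1, n // 2 + 1)
    odd = k[k % 2 == 1]
    h[odd] = -1.0 / (np.pi * odd * du) ** 2
    h[-odd] = h[odd]
    return h


def _filter_sinogram(sino: Sinogram, window: str) -> np.ndarray:
    """Cosine weighting + row-wise ramp filtering, in isocenter-plane units."""
    geom = sino.geometry
    sdd = geom.source_to_detector
    u = (np.arange(geom.n_channels) - (geom.n_channels - 1) / 2.0) * geom.channel_width
    w = (np.arange(geom.n_rows) - (geom.n_rows - 1) / 2.0) * geom.row_height
    cosw = sdd / np.sqrt(sdd * sdd + u[None, :] ** 2 + w[:, None] ** 2)
    du = geom.channel_width * geom.source_radius / sdd  # channel pitch at iso
    nfft = 1 << int(np.ceil(np.log2(max(2 * geom.n_channels, 16))))
    hf = np.fft.rfft(_ramp_kernel(nfft, du))
    freqs = np.fft.rfftfreq(nfft, d=du)
    fny = 1.0 / (2.0 * du)
    if window == "cosine":
        hf = hf * np.cos(0.5 * np.pi * freqs / fny)
    elif window == "hann":
        hf = hf * (0.5 + 0.5 * np.cos(np.pi * freqs / fny))
    elif window != "none":
        raise ValidationError(f"unknown filter window {window!r}")
    pw = sino.data * cosw[None, :, :]
    spec = np.fft.rfft(pw, n=nfft, axis=2) * hf[None, None, :]
    filt = np.fft.irfft(spec, n=nfft, axis=2)[:, :, :geom.n_channels] * du
    return np.ascontiguousarray(filt)


@njit(cache=True)
def _fdk_backproject(q, src, det_c, e_u, e_v, R, sdd, n_rows, n_channels,
                     row_height, channel_width, nx, ny, nz,
                     spx, spy, spz, ox, oy, oz, out, counts):
    n_views = src.shape[0]
    mag = sdd / R  # iso-plane -> physical detector
    for i in range(nx):
        x = ox + (i - (nx - 1) / 2.0) * spx
        for j in range(ny):
            y = oy + (j - (ny - 1) / 2.0) * spy
            for k in range(nz):
                z = oz + (k - (nz - 1) / 2.0) * spz
                acc = 0.0
                cnt = 0
                for view in range(n_views):
                    rx = x - src[view, 0]
                    ry = y - src[view, 1]
                    rz = z - src[view, 2]
                    dcx = det_c[view, 0] - src[view, 0]
                    dcy = det_c[view, 1] - src[view, 1]
                    dcz = det_c[view, 2] - src[view, 2]
                    dn = np.sqrt(dcx * dcx + dcy * dcy + dcz * dcz)
                    l = (rx * dcx + ry * dcy + rz * dcz) / dn
                    if l <= 1e-6:
                        continue
                    m = R / l
                    u_iso = (rx * e_u[view, 0] + ry * e_u[view, 1] + rz * e_u[view, 2]) * m
                    v_iso = (rx * e_v[view, 0] + ry * e_v[view, 1] + rz * e_v[view, 2]) * m
                    row_f = v_iso * mag / row_height + (n_rows - 1) / 2.0
                    if row_f < 0.0 or row_f > n_rows - 1:
                        continue  # outside this view's z-window
                    cnt += 1
                    ch_f = u_iso * mag / channel_width + (n_channels - 1) / 2.0
                    if ch_f < 0.0 or ch_f > n_channels - 1:
                        continue  # laterally outside the fan: contributes 0
                    r0 = int(np.floor(row_f))
                    c0 = int(np.floor(ch_f))
                    if r0 == n_rows - 1:
                        r0 -= 1
                    if c0 == n_channels - 1:
                        c0 -= 1
                    wr = row_f - r0
                    wc = ch_f - c0
                    val = (q[view, r0, c0] * (1 - wr) * (1 - wc)
                           + q[view, r0, c0 + 1] * (1 - wr) * wc
                           + q[view, r0 + 1, c0] * wr * (1 - wc)
                           + q[view, r0 + 1, c0 + 1] * wr * wc)
                    acc += m * m * val
                counts[i, j, k] = cnt
                if cnt > 0:
                    out[i, j, k] = np.pi / cnt * acc


def fdk_reconstruct(sino: Sinogram, grid: VolumeGrid, *, window: str = "cosine") -> Volume:
    """Simplified helical FDK: approximate analytic baseline reconstruction."""
    geom = sino.geometry
    if geom.n_views < geom.views_per_rotation:
        raise ValidationError("fdk_reconstruct needs at least one full rotation of data")
    filt = _filter_sinogram(sino, window)
    src, det_c, e_u, e_v = view_arrays(geom)
    out = np.zeros(grid.shape)
    counts = np.zeros(grid.shape, dtype=np.int64)
    _fdk_backproject(filt, src, det_c, e_u, e_v,
                     geom.source_radius, geom.source_to_detector,
                     geom.n_rows, geom.n_channels,
                     geom.row_height, geom.channel_width,
                     grid.n_x, grid.n_y, grid.n_z,
                     grid.spacing_x, grid.spacing_y, grid.spacing_z,
                     float(grid.origin[0]), float(grid.origin[1]), float(grid.origin[2]),
                     out, counts)
    uncovered = np.where(~counts.any(axis=(0, 1)))[0]
    if uncovered.size:
        raise ValidationError(
            f"insufficient z-coverage: no views reach slices {uncovered.tolist()}")
    return Volume(out, grid)
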