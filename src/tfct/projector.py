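"""Matched helical cone-beam projector pair (Joseph's method).

``forward_project`` integrates the trilinearly interpolated volume along the
single infinitely-narrow ray from the (possibly FFS-deflected) source to each
detector-cell center: the driving axis is the one the ray crosses fastest in
index units, and at each voxel slab the two transverse coordinates are
bilinearly interpolated.  ``back_project`` scatters with the *identical*
weights, so the pair is an exact numerical adjoint (up to float rounding),
which is what the iterative solver requires.

Rays that miss the grid contribute zero.  All physical lengths are mm; volume
values are attenuation in mm^-1, so line integrals are dimensionless.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import ValidationError
from .geometry import ScanGeometry, Sinogram, view_arrays
from .grid import Volume, VolumeGrid

__all__ = ["forward_project", "back_project"]


@njit(cache=True, fastmath=True, inline="always")
def _slab_range(n0, a, b, n1):
    """Slab indices i in [0, n0) where a + i*b lies in (-1, n1): [lo, hi)."""
    lo, hi = 0, n0
    if b > 1e-300:
        lo = max(lo, int(np.ceil((-1.0 - a) / b + 1e-12)))
        hi = min(hi, int(np.floor((n1 - a) / b - 1e-12)) + 1)
    elif b < -1e-300:
        lo = max(lo, int(np.ceil((n1 - a) / b + 1e-12)))
        hi = min(hi, int(np.floor((-1.0 - a) / b - 1e-12)) + 1)
    elif a <= -1.0 or a >= n1:
        return 0, 0
    return lo, hi


@njit(cache=True, fastmath=True)
def _line_forward(vol, n0, n1, n2, sp0, sp1, sp2, o0, o1, o2,
                  s0, s1, s2, d0, d1, d2, norm):
    """Line integral with driving axis = axis 0 of ``vol`` (a permuted view)."""
    step = sp0 * norm / abs(d0)
    dt = sp0 / d0
    t0 = (o0 - (n0 - 1) / 2.0 * sp0 - s0) / d0  # parameter at slab i = 0
    a1 = (s1 + t0 * d1 - o1) / sp1 + (n1 - 1) / 2.0
    a2 = (s2 + t0 * d2 - o2) / sp2 + (n2 - 1) / 2.0
    b1 = dt * d1 / sp1
    b2 = dt * d2 / sp2
    lo1, hi1 = _slab_range(n0, a1, b1, n1)
    lo2, hi2 = _slab_range(n0, a2, b2, n2)
    lo = max(lo1, lo2)
    hi = min(hi1, hi2)
    acc = 0.0
    f1 = a1 + lo * b1
    f2 = a2 + lo * b2
    for i in range(lo, hi):
        i1 = int(np.floor(f1))
        i2 = int(np.floor(f2))
        w1 = f1 - i1
        w2 = f2 - i2
        if 0 <= i1 < n1:
            if 0 <= i2 < n2:
                acc += vol[i, i1, i2] * (1.0 - w1) * (1.0 - w2)
            if 0 <= i2 + 1 < n2:
                acc += vol[i, i1, i2 + 1] * (1.0 - w1) * w2
        if 0 <= i1 + 1 < n1:
            if 0 <= i2 < n2:
                acc += vol[i, i1 + 1, i2] * w1 * (1.0 - w2)
            if 0 <= i2 + 1 < n2:
                acc += vol[i, i1 + 1, i2 + 1] * w1 * w2
        f1 += b1
        f2 += b2
    return acc * step


@njit(cache=True, fastmath=True)
def _line_back(vol, n0, n1, n2, sp0, sp1, sp2, o0, o1, o2,
               s0, s1, s2, d0, d1, d2, norm, val):
    """Transposed scatter of :func:`_line_forward` (same weights)."""
    step = sp0 * norm / abs(d0)
    v = val * step
    dt = sp0 / d0
    t0 = (o0 - (n0 - 1) / 2.0 * sp0 - s0) / d0
    a1 = (s1 + t0 * d1 - o1) / sp1 + (n1 - 1) / 2.0
    a2 = (s2 + t0 * d2 - o2) / sp2 + (n2 - 1) / 2.0
    b1 = dt * d1 / sp1
    b2 = dt * d2 / sp2
    lo1, hi1 = _slab_range(n0, a1, b1, n1)
    lo2, hi2 = _slab_range(n0, a2, b2, n2)
    lo = max(lo1, lo2)
    hi = min(hi1, hi2)
    f1 = a1 + lo * b1
    f2 = a2 + lo * b2
    for i in range(lo, hi):
        i1 = int(np.floor(f1))
        i2 = int(np.floor(f2))
        w1 = f1 - i1
        w2 = f2 - i2
        if 0 <= i1 < n1:
            if 0 <= i2 < n2:
                vol[i, i1, i2] += v * (1.0 - w1) * (1.0 - w2)
            if 0 <= i2 + 1 < n2:
                vol[i, i1, i2 + 1] += v * (1.0 - w1) * w2
        if 0 <= i1 + 1 < n1:
            if 0 <= i2 < n2:
                vol[i, i1 + 1, i2] += v * w1 * (1.0 - w2)
            if 0 <= i2 + 1 < n2:
                vol[i, i1 + 1, i2 + 1] += v * w1 * w2
        f1 += b1
        f2 += b2


@njit(cache=True, fastmath=True)
def _project_views(mode, vol_x, vol_y, vol_z, nx, ny, nz,
                   spx, spy, spz, ox, oy, oz,
                   src, det_c, e_u, e_v, n_rows, n_channels,
                   row_height, channel_width, sino):
    """mode 0: forward (fill sino); mode 1: back (scatter sino into volume).

    ``vol_x/y/z`` are views of one array permuted so the driving axis is
    first: (x,y,z), (y,z,x), (z,x,y).
    """
    n_views = src.shape[0]
    for view in range(n_views):
        sx, sy, sz = src[view, 0], src[view, 1], src[view, 2]
        for r in range(n_rows):
            wv = (r - (n_rows - 1) / 2.0) * row_height
            for c in range(n_channels):
                wu = (c - (n_channels - 1) / 2.0) * channel_width
                px = det_c[view, 0] + wu * e_u[view, 0] + wv * e_v[view, 0]
                py = det_c[view, 1] + wu * e_u[view, 1] + wv * e_v[view, 1]
                pz = det_c[view, 2] + wu * e_u[view, 2] + wv * e_v[view, 2]
                dx, dy, dz = px - sx, py - sy, pz - sz
                norm = np.sqrt(dx * dx + dy * dy + dz * dz)
                ax, ay, az = abs(dx) / spx, abs(dy) / spy, abs(dz) / spz
                if mode == 0:
                    if ax >= ay and ax >= az:
                        val = _line_forward(vol_x, nx, ny, nz, spx, spy, spz,
                                            ox, oy, oz, sx, sy, sz, dx, dy, dz, norm)
                    elif ay >= az:
                        val = _line_forward(vol_y, ny, nz, nx, spy, spz, spx,
                                            oy, oz, ox, sy, sz, sx, dy, dz, dx, norm)
                    else:
                        val = _line_forward(vol_z, nz, nx, ny, spz, spx, spy,
                                            oz, ox, oy, sz, sx, sy, dz, dx, dy, norm)
                    sino[view, r, c] = val
                else:
                    val = sino[view, r, c]
                    if val != 0.0:
                        if ax >= ay and ax >= az:
                            _line_back(vol_x, nx, ny, nz, spx, spy, spz,
                                       ox, oy, oz, sx, sy, sz, dx, dy, dz, norm, val)
                        elif ay >= az:
                            _line_back(vol_y, ny, nz, nx, spy, spz, spx,
                                       oy, oz, ox, sy, sz, sx, dy, dz, dx, norm, val)
                        else:
                            _line_back(vol_z, nz, nx, ny, spz, spx, spy,
                                       oz, ox, oy, sz, sx, sy, dz, dx, dy, norm, val)


def _run(mode: int, vol_data: np.ndarray, grid: VolumeGrid,
         geometry: ScanGeometry, sino_data: np.ndarray) -> None:
    src, det_c, e_u, e_v = view_arrays(geometry)
    # contiguous per-driving-axis layouts keep the bilinear reads cache-local
    if mode == 0:
        vol_x = np.ascontiguousarray(vol_data)
        vol_y = np.ascontiguousarray(vol_data.transpose(1, 2, 0))
        vol_z = np.ascontiguousarray(vol_data.transpose(2, 0, 1))
    else:
        vol_x = np.zeros(vol_data.shape)
        vol_y = np.zeros((vol_data.shape[1], vol_data.shape[2], vol_data.shape[0]))
        vol_z = np.zeros((vol_data.shape[2], vol_data.shape[0], vol_data.shape[1]))
    ox, oy, oz = grid.origin
    _project_views(mode, vol_x, vol_y, vol_z, grid.n_x, grid.n_y, grid.n_z,
                   grid.spacing_x, grid.spacing_y, grid.spacing_z,
                   float(ox), float(oy), float(oz),
                   src, det_c, e_u, e_v,
                   geometry.n_rows, geometry.n_channels,
                   geometry.row_height, geometry.channel_width, sino_data)
    if mode == 1:
        vol_data += vol_x
        vol_data += vol_y.transpose(2, 0, 1)
        vol_data += vol_z.transpose(1, 2, 0)


def forward_project(volume: Volume, geometry: ScanGeometry) -> Sinogram:
    """Apply the system matrix A: volume -> sinogram of line integrals."""
    if not np.all(np.isfinite(volume.data)):
        raise ValidationError("volume contains non-finite values")
    sino = np.zeros((geometry.n_views, geometry.n_rows, geometry.n_channels))
    _run(0, np.ascontiguousarray(volume.data), volume.grid, geometry, sino)
    return Sinogram(sino, geometry)


def back_project(sino: Sinogram, grid: VolumeGrid) -> Volume:
    """Apply the exact numerical transpose A^T: sinogram -> volume."""
    if not np.all(np.isfinite(sino.data)):
        raise ValidationError("sinogram contains non-finite values")
    vol = np.zeros(grid.shape)
    _run(1, vol, grid, sino.geometry, np.ascontiguousarray(sino.data))
    return Volume(vol, grid)
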