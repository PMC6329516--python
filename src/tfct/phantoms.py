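"""Synthetic phantoms, helical scan simulation, and sparse-view subsampling.

Phantoms are sums of analytically defined ellipsoids (additive attenuation,
mm^-1), emulating the water-cylinder-with-inserts style of CT accreditation
phantoms.  Dose is modeled through the incident photon count I0 per detector
cell: a transmission measurement N ~ Poisson(I0 * exp(-p)) (plus optional
Gaussian electronic noise), clamped at 1 count, gives the noisy line
integral p_hat = ln(I0 / N).  Sparse-view protocols keep every ``step``-th
view and rescale the geometry, which is equivalent to spinning the gantry
and feeding the table ``step`` times faster.

The default desk-scale geometry is a scaled-down replica of a 64-row
clinical helical acquisition (pitch 1, z-flying focal spot optional): a
64 x 64 x 32 grid, 16 detector rows, 96 channels and 96 views per rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .geometry import ScanGeometry, Sinogram
from .grid import Volume, VolumeGrid
from .projector import forward_project

__all__ = [
    "EllipsoidSpec",
    "PhantomSpec",
    "NoiseModel",
    "add_noise",
    "rasterize",
    "simulate_scan",
    "subsample_views",
    "desk_geometry",
    "desk_grid",
    "two_ellipsoid_phantom",
    "acr_like_phantom",
    "parse_phantom_text",
    "phantom_to_text",
]

log = logging.getLogger(__name__)

# I0 presets standing in for tube-voltage dose levels (photons per cell).
DOSE_PRESETS = {"80kV": 2.0e4, "100kV": 5.0e4, "120kV": 1.0e5, "140kV": 2.0e5}


@dataclass(frozen=True)
class EllipsoidSpec:
    """One additive ellipsoid: center/semi-axes in mm, z-rotation in radians."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    attenuation: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValidationError("ellipsoid semi-axes must be > 0")

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        ct, st = np.cos(self.rotation), np.sin(self.rotation)
        xr = (x - cx) * ct + (y - cy) * st
        yr = -(x - cx) * st + (y - cy) * ct
        return (xr / ax) ** 2 + (yr / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """A list of additive ellipsoids; composite attenuation must be >= 0."""

    ellipsoids: tuple[EllipsoidSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipsoids", tuple(self.ellipsoids))


@dataclass(frozen=True)
class NoiseModel:
    """Poisson transmission noise at incident count I0, optional Gaussian sigma."""

    i0: float
    sigma_electronic: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValidationError("incident photon count I0 must be > 0")
        if self.sigma_electronic < 0:
            raise ValidationError("electronic noise sigma must be >= 0")


def rasterize(spec: PhantomSpec, grid: VolumeGrid, *, supersample: int = 2) -> Volume:
    """Sample the analytic phantom on voxel centers (``supersample`` x per axis)."""
    if supersample < 1:
        raise ValidationError("supersample must be >= 1")
    out = np.zeros(grid.shape)
    # supersample offsets within one voxel, centered
    offs = (np.arange(supersample) - (supersample - 1) / 2.0) / supersample
    cx, cy, cz = grid.meshgrid_world()
    for ox in offs * grid.spacing_x:
        for oy in offs * grid.spacing_y:
            for oz in offs * grid.spacing_z:
                for e in spec.ellipsoids:
                    out += e.attenuation * e.contains(cx + ox, cy + oy, cz + oz)
    out /= supersample ** 3
    if np.any(out < -1e-12):
        raise ValidationError("composite phantom attenuation is negative somewhere")
    return Volume(out, grid)


def simulate_scan(spec: PhantomSpec, geometry: ScanGeometry,
                  noise: NoiseModel | None = None, *,
                  grid: VolumeGrid | None = None,
                  supersample: int = 2) -> Sinogram:
    """Forward-project the rasterized phantom; optionally add transmission noise."""
    if grid is None:
        grid = desk_grid()
    clean = forward_project(rasterize(spec, grid, supersample=supersample), geometry)
    if noise is None:
        return clean
    return add_noise(clean, noise)


def add_noise(sino: Sinogram, noise: NoiseModel) -> Sinogram:
    """Apply the Poisson transmission noise model to clean line integrals."""
    rng = np.random.default_rng(noise.seed)
    transmitted = noise.i0 * np.exp(-sino.data)
    counts = rng.poisson(transmitted).astype(np.float64)
    if noise.sigma_electronic > 0:
        counts = counts + rng.normal(0.0, noise.sigma_electronic, size=counts.shape)
    clamped = counts < 1.0
    frac = float(clamped.mean())
    if frac > 0.01:
        log.warning("photon starvation: %.2f%% of detector cells clamped to 1 count "
                    "(I0=%.3g too low for this object)", 100 * frac, noise.i0)
    counts = np.maximum(counts, 1.0)
    return Sinogram(np.log(noise.i0 / counts), sino.geometry)


def subsample_views(sino: Sinogram, step: int) -> Sinogram:
    """Uniform sparse-view protocol: keep views with index = 0 (mod step).

    The returned geometry has views_per_rotation / step views per 360 degrees
    with the angular and table steps rescaled accordingly.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    if step == 1:
        return sino.copy()
    geom = sino.geometry
    if geom.views_per_rotation % step != 0:
        raise ValidationError(
            f"step {step} does not divide views_per_rotation {geom.views_per_rotation}")
    kept = np.arange(0, geom.n_views, step)
    ffs = geom.ffs_schedule[kept] if geom.ffs_schedule is not None else None
    new_geom = replace(
        geom,
        views_per_rotation=geom.views_per_rotation // step,
        n_views=len(kept),
        z_start=geom.z0,  # pin the original start so kept views keep their z
        ffs_schedule=ffs,
    )
    return Sinogram(sino.data[kept], new_geom)


# ---------------------------------------------------------------------------
# Desk-scale presets
# ---------------------------------------------------------------------------

def desk_grid(n_xy: int = 64, n_z: int = 32, spacing: float = 2.0) -> VolumeGrid:
    """Default desk-scale grid: 64 x 64 x 32 voxels at 2 mm."""
    return VolumeGrid(n_xy, n_xy, n_z, spacing, spacing, spacing)


def desk_geometry(n_turns: float = 2.0, *, views_per_rotation: int = 96,
                  n_rows: int = 16, n_channels: int = 96,
                  pitch: float = 1.0, ffs_delta_z: float = 0.0) -> ScanGeometry:
    """Desk-scale helical scan: pitch-1, 96 views/rotation, 16 x 96 panel.

    Source radius 300 mm, panel at 600 mm, 4 mm cells: the fan covers a
    96 mm-radius field of view at the isocenter, enclosing the default grid.
    """
    n_views = int(round(n_turns * views_per_rotation))
    geom = ScanGeometry(
        source_radius=300.0, source_to_detector=600.0,
        n_rows=n_rows, n_channels=n_channels,
        row_height=4.0, channel_width=4.0,
        views_per_rotation=views_per_rotation, n_views=n_views,
        pitch=pitch,
    )
    if ffs_delta_z != 0.0:
        from .geometry import ffs_z_schedule
        geom = geom.with_ffs(ffs_z_schedule(n_views, ffs_delta_z))
    return geom


def two_ellipsoid_phantom() -> PhantomSpec:
    """Piecewise-constant body + insert, the standard small recovery target."""
    return PhantomSpec((
        EllipsoidSpec(center=(0.0, 0.0, 0.0), semi_axes=(44.0, 36.0, 26.0),
                      attenuation=0.02),
        EllipsoidSpec(center=(12.0, 6.0, 0.0), semi_axes=(14.0, 10.0, 9.0),
                      attenuation=0.01, rotation=0.5),
    ))


def acr_like_phantom() -> PhantomSpec:
    """Water cylinder + three insert rods + air pocket + high-contrast edge block.

    A desk-scale stand-in for a CT accreditation phantom; the dense block
    provides the sharp edge used for ESF/MTF measurement.
    """
    water = 0.02
    return PhantomSpec((
        # body "cylinder" (long ellipsoid along z)
        EllipsoidSpec(center=(0.0, 0.0, 0.0), semi_axes=(54.0, 54.0, 30.0),
                      attenuation=water),
        # insert rods (contrasts relative to water)
        EllipsoidSpec(center=(-24.0, 18.0, 0.0), semi_axes=(7.0, 7.0, 24.0),
                      attenuation=0.010),
        EllipsoidSpec(center=(24.0, 18.0, 0.0), semi_axes=(7.0, 7.0, 24.0),
                      attenuation=0.005),
        EllipsoidSpec(center=(0.0, -28.0, 0.0), semi_axes=(7.0, 7.0, 24.0),
                      attenuation=-0.010),
        # air pocket
        EllipsoidSpec(center=(-20.0, -20.0, 0.0), semi_axes=(6.0, 6.0, 18.0),
                      attenuation=-water),
        # high-contrast edge block for the MTF edge profile
        EllipsoidSpec(center=(20.0, -10.0, 0.0), semi_axes=(10.0, 10.0, 20.0),
                      attenuation=0.030),
    ))


# ---------------------------------------------------------------------------
# Plain-text phantom spec files: one ellipsoid per line,
#   cx cy cz  ax ay az  rotation  attenuation
# ---------------------------------------------------------------------------

def parse_phantom_text(text: str) -> PhantomSpec:
    ellipsoids = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 8:
            raise ValidationError(
                f"phantom line {lineno}: expected 8 columns "
                "(cx cy cz ax ay az rotation attenuation), got "
                f"{len(parts)}")
        vals = [float(p) for p in parts]
        ellipsoids.append(EllipsoidSpec(center=tuple(vals[0:3]),
                                        semi_axes=tuple(vals[3:6]),
                                        rotation=vals[6], attenuation=vals[7]))
    return PhantomSpec(tuple(ellipsoids))


def phantom_to_text(spec: PhantomSpec) -> str:
    lines = ["# cx cy cz  ax ay az  rotation  attenuation"]
    for e in spec.ellipsoids:
        lines.append("  ".join([
            " ".join(f"{v:g}" for v in e.center),
            " ".join(f"{v:g}" for v in e.semi_axes),
            f"{e.rotation:g}", f"{e.attenuation:g}"]))
    return "\n".join(lines) + "\n"
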