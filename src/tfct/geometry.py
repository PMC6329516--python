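"""Helical cone-beam scan geometry.

The source travels a helix: at view ``v`` it sits at angle
``theta_v = start_angle + v * 2*pi / views_per_rotation`` and axial position
``z_v = z_start + v * dz`` with ``dz = pitch * collimation / views_per_rotation``
(pitch = table feed per rotation / total collimation, collimation measured at
the isocenter).  A flat equispaced detector panel is rigidly attached to the
gantry, centered on the nominal ray from source through the isocenter; an
optional flying-focal-spot (FFS) schedule deflects the *source* per view in
the radial and/or z direction while the panel stays put.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "ScanGeometry",
    "Sinogram",
    "source_pose",
    "ffs_z_schedule",
    "geometry_to_config",
    "geometry_from_config",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Helical multi-row scan description (mm, radians, dimensionless pitch)."""

    source_radius: float
    source_to_detector: float
    n_rows: int
    n_channels: int
    row_height: float
    channel_width: float
    views_per_rotation: int
    n_views: int
    pitch: float = 1.0
    start_angle: float = 0.0
    z_start: float | None = None  # None -> helix centered on z = 0
    # (n_views, 2) per-view source offsets in mm: column 0 radial, column 1 z.
    ffs_schedule: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.source_radius <= 0 or self.source_to_detector <= self.source_radius:
            raise ValidationError(
                "need 0 < source_radius < source_to_detector (flat panel beyond isocenter)"
            )
        if min(self.n_rows, self.n_channels) < 1 or min(self.row_height, self.channel_width) <= 0:
            raise ValidationError("detector grid counts >= 1 and cell sizes > 0 required")
        if self.views_per_rotation < 1 or self.n_views < 1:
            raise ValidationError("view counts must be >= 1")
        if self.pitch <= 0:
            raise ValidationError("pitch must be > 0 (angular and z steps strictly positive)")
        if self.ffs_schedule is not None:
            ffs = np.asarray(self.ffs_schedule, dtype=float)
            if ffs.shape != (self.n_views, 2):
                raise ValidationError(
                    f"ffs_schedule must have shape ({self.n_views}, 2), got {ffs.shape}"
                )
            object.__setattr__(self, "ffs_schedule", ffs)

    # -- derived quantities -------------------------------------------------
    @property
    def angular_step(self) -> float:
        return 2.0 * np.pi / self.views_per_rotation

    @property
    def collimation(self) -> float:
        """Total collimation at the isocenter: n_rows * row height scaled to iso."""
        scale = self.source_radius / self.source_to_detector
        return self.n_rows * self.row_height * scale

    @property
    def z_advance_per_view(self) -> float:
        return self.pitch * self.collimation / self.views_per_rotation

    @property
    def z0(self) -> float:
        if self.z_start is not None:
            return self.z_start
        return -0.5 * (self.n_views - 1) * self.z_advance_per_view

    @property
    def fov_radius(self) -> float:
        """Half-width of the detector fan re-projected to the isocenter."""
        scale = self.source_radius / self.source_to_detector
        return 0.5 * self.n_channels * self.channel_width * scale

    def ffs(self) -> np.ndarray:
        if self.ffs_schedule is None:
            return np.zeros((self.n_views, 2))
        return self.ffs_schedule

    def with_ffs(self, schedule: np.ndarray) -> "ScanGeometry":
        return replace(self, ffs_schedule=np.asarray(schedule, dtype=float))


def ffs_z_schedule(n_views: int, delta_z: float) -> np.ndarray:
    """Alternating +/- delta_z z-flying-focal-spot schedule (radial column zero)."""
    sched = np.zeros((n_views, 2))
    sched[0::2, 1] = delta_z
    sched[1::2, 1] = -delta_z
    return sched


def source_pose(geometry: ScanGeometry, view: int) -> tuple[np.ndarray, np.ndarray]:
    """Source position (mm) and detector orientation frame at one view.

    Returns ``(pos, frame)`` where ``frame`` rows are the orthonormal detector
    axes ``e_u`` (channel direction, tangential), ``e_v`` (row direction, +z)
    and ``e_w`` (unit vector from isocenter toward the nominal source).
    """
    if not 0 <= view < geometry.n_views:
        raise IndexError(f"view {view} out of range [0, {geometry.n_views})")
    theta = geometry.start_angle + view * geometry.angular_step
    e_w = np.array([np.cos(theta), np.sin(theta), 0.0])
    e_u = np.array([-np.sin(theta), np.cos(theta), 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    z = geometry.z0 + view * geometry.z_advance_per_view
    radial, dz = geometry.ffs()[view]
    pos = (geometry.source_radius + radial) * e_w + np.array([0.0, 0.0, z + dz])
    return pos, np.vstack([e_u, e_v, e_w])


def detector_center(geometry: ScanGeometry, view: int) -> np.ndarray:
    """Center of the flat panel (attached to the nominal gantry, no FFS)."""
    theta = geometry.start_angle + view * geometry.angular_step
    e_w = np.array([np.cos(theta), np.sin(theta), 0.0])
    z = geometry.z0 + view * geometry.z_advance_per_view
    d = geometry.source_to_detector - geometry.source_radius
    return -d * e_w + np.array([0.0, 0.0, z])


def view_arrays(geometry: ScanGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-view source positions, detector centers and panel axes."""
    v = np.arange(geometry.n_views)
    theta = geometry.start_angle + v * geometry.angular_step
    cw = np.cos(theta)
    sw = np.sin(theta)
    z = geometry.z0 + v * geometry.z_advance_per_view
    ffs = geometry.ffs()
    src = np.stack(
        [(geometry.source_radius + ffs[:, 0]) * cw,
         (geometry.source_radius + ffs[:, 0]) * sw,
         z + ffs[:, 1]], axis=1)
    d = geometry.source_to_detector - geometry.source_radius
    det_c = np.stack([-d * cw, -d * sw, z], axis=1)
    e_u = np.stack([-sw, cw, np.zeros_like(cw)], axis=1)
    e_v = np.broadcast_to(np.array([0.0, 0.0, 1.0]), (geometry.n_views, 3)).copy()
    return src, det_c, e_u, e_v


@dataclass
class Sinogram:
    """Projection data: line integrals, shape (n_views, n_rows, n_channels)."""

    data: np.ndarray
    geometry: ScanGeometry = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.n_rows, self.geometry.n_channels)
        if self.data.shape != expected:
            raise ValidationError(
                f"sinogram shape {self.data.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("sinogram contains non-finite values")

    def copy(self) -> "Sinogram":
        return Sinogram(self.data.copy(), self.geometry)


# -- flat key-value config serialization -----------------------------------

_SCALAR_FIELDS = [
    "source_radius", "source_to_detector", "n_rows", "n_channels",
    "row_height", "channel_width", "views_per_rotation", "n_views",
    "pitch", "start_angle",
]
_INT_FIELDS = {"n_rows", "n_channels", "views_per_rotation", "n_views"}


def geometry_to_config(geom: ScanGeometry) -> str:
    """Serialize to a flat ``key = value`` text block (keys = field names)."""
    lines = [f"{k} = {getattr(geom, k)!r}" for k in _SCALAR_FIELDS]
    if geom.z_start is not None:
        lines.append(f"z_start = {geom.z_start!r}")
    if geom.ffs_schedule is not None and np.any(geom.ffs_schedule):
        rows = [",".join(repr(float(x)) for x in row) for row in geom.ffs_schedule]
        lines.append("ffs_schedule = " + ";".join(rows))
    return "\n".join(lines) + "\n"


def geometry_from_config(text: str) -> ScanGeometry:
    kv: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"malformed geometry config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key] = val
    missing = [k for k in _SCALAR_FIELDS if k not in kv]
    if missing:
        raise ValidationError(f"geometry config missing keys: {missing}")
    kwargs: dict = {}
    for k in _SCALAR_FIELDS:
        kwargs[k] = int(kv[k]) if k in _INT_FIELDS else float(kv[k])
    if "z_start" in kv:
        kwargs["z_start"] = float(kv["z_start"])
    if "ffs_schedule" in kv:
        rows = [[float(x) for x in row.split(",")] for row in kv["ffs_schedule"].split(";")]
        kwargs["ffs_schedule"] = np.array(rows)
    return ScanGeometry(**kwargs)
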