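"""Readers/writers binding the pipeline together.

Sinograms live in an HDF5 container: dataset ``projections``
(n_views x n_rows x n_channels, float32) with the geometry carried as
attributes (one per field; the FFS schedule, when present, as its own
dataset).  Volumes are written as NIfTI (spacing in the header) and as raw
32-bit float with a plain-text sidecar header.  All writes are atomic
(write to a temp file in the target directory, then rename).
"""

from __future__ import annotations

import contextlib
import csv
import json
import os
import tempfile
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .errors import ValidationError
from .framelet import FrameletCoeffs
from .geometry import ScanGeometry, Sinogram, _INT_FIELDS, _SCALAR_FIELDS
from .grid import Volume, VolumeGrid

__all__ = [
    "write_sinogram", "read_sinogram",
    "write_volume_nifti", "read_volume_nifti",
    "write_volume_raw", "read_volume_raw",
    "write_framelet_coeffs", "read_framelet_coeffs",
    "write_metrics_csv", "write_manifest", "read_manifest",
    "atomic_path",
]


@contextlib.contextmanager
def atomic_path(target: str | Path):
    """Yield a temp path in the target's directory; rename into place on success."""
    target = Path(target)
    target.parent.mkdir(parents=True, exist_ok=True)
    # keep the target's extension so format-sniffing writers behave
    fd, tmp = tempfile.mkstemp(dir=target.parent, prefix=".tmp.",
                               suffix="".join(target.suffixes) or ".tmp")
    os.close(fd)
    try:
        yield Path(tmp)
        os.replace(tmp, target)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_sinogram(path: str | Path, sino: Sinogram) -> None:
    geom = sino.geometry
    with atomic_path(path) as tmp:
        with h5py.File(tmp, "w") as f:
            ds = f.create_dataset("projections", data=sino.data.astype(np.float32))
            for k in _SCALAR_FIELDS:
                ds.attrs[k] = getattr(geom, k)
            ds.attrs["z_start"] = geom.z0  # resolved value: round-trips exactly
            if geom.ffs_schedule is not None and np.any(geom.ffs_schedule):
                f.create_dataset("ffs_schedule", data=geom.ffs_schedule)


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"sinogram file not found: {path}")
    with h5py.File(path, "r") as f:
        if "projections" not in f:
            raise ValidationError(f"{path}: missing 'projections' dataset")
        ds = f["projections"]
        kwargs = {}
        for k in _SCALAR_FIELDS:
            if k not in ds.attrs:
                raise ValidationError(f"{path}: missing geometry attribute {k!r}")
            kwargs[k] = int(ds.attrs[k]) if k in _INT_FIELDS else float(ds.attrs[k])
        kwargs["z_start"] = float(ds.attrs["z_start"]) if "z_start" in ds.attrs else None
        if "ffs_schedule" in f:
            kwargs["ffs_schedule"] = np.asarray(f["ffs_schedule"])
        data = np.asarray(ds, dtype=np.float64)
    return Sinogram(data, ScanGeometry(**kwargs))


def _affine(grid: VolumeGrid) -> np.ndarray:
    aff = np.diag([grid.spacing_x, grid.spacing_y, grid.spacing_z, 1.0])
    corner = grid.index_to_world(np.zeros(3))
    aff[:3, 3] = corner
    return aff


def write_volume_nifti(path: str | Path, vol: Volume) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.grid))
    img.header.set_zooms((vol.grid.spacing_x, vol.grid.spacing_y, vol.grid.spacing_z))
    with atomic_path(path) as tmp:
        nib.save(img, str(tmp))


def read_volume_nifti(path: str | Path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume")
    zooms = img.header.get_zooms()[:3]
    # recover the center offset from the corner translation
    corner = img.affine[:3, 3]
    center = corner + (np.array(data.shape) - 1) / 2.0 * np.array(zooms)
    grid = VolumeGrid(*data.shape, *[float(z) for z in zooms],
                      origin=tuple(float(c) for c in center))
    return Volume(data, grid)


def write_volume_raw(path: str | Path, vol: Volume) -> None:
    """Raw little-endian float32 (C order, index [i, j, k]) + text sidecar."""
    path = Path(path)
    with atomic_path(path) as tmp:
        vol.data.astype("<f4").tofile(tmp)
    hdr = {
        "dtype": "float32-le", "order": "C", "axes": "x,y,z",
        "n_x": vol.grid.n_x, "n_y": vol.grid.n_y, "n_z": vol.grid.n_z,
        "spacing_x": vol.grid.spacing_x, "spacing_y": vol.grid.spacing_y,
        "spacing_z": vol.grid.spacing_z,
        "origin": ",".join(str(v) for v in vol.grid.origin),
    }
    with atomic_path(path.with_suffix(path.suffix + ".hdr")) as tmp:
        tmp.write_text("".join(f"{k} = {v}\n" for k, v in hdr.items()))


def read_volume_raw(path: str | Path) -> Volume:
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    for p in (path, hdr_path):
        if not p.exists():
            raise ValidationError(f"raw volume file not found: {p}")
    kv = {}
    for line in hdr_path.read_text().splitlines():
        if "=" in line:
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
    shape = (int(kv["n_x"]), int(kv["n_y"]), int(kv["n_z"]))
    origin = tuple(float(x) for x in kv["origin"].split(","))
    grid = VolumeGrid(*shape, float(kv["spacing_x"]), float(kv["spacing_y"]),
                      float(kv["spacing_z"]), origin=origin)
    data = np.fromfile(path, dtype="<f4").astype(np.float64)
    if data.size != np.prod(shape):
        raise ValidationError(f"{path}: size does not match header dimensions")
    return Volume(data.reshape(shape), grid)


def write_framelet_coeffs(path: str | Path, coeffs: FrameletCoeffs) -> None:
    """One dataset per level/band/axis, names 'L{l}_B{j}_{axis}' and 'lowpass'."""
    axes = "xyz"
    with atomic_path(path) as tmp:
        with h5py.File(tmp, "w") as f:
            f.attrs["levels"] = coeffs.levels
            f.attrs["shape"] = coeffs.shape
            for l0, lev in enumerate(coeffs.bands, start=1):
                for j in (1, 2):
                    for a in range(3):
                        f.create_dataset(f"L{l0}_B{j}_{axes[a]}",
                                         data=lev[j][a].astype(np.float32))
            for a in range(3):
                f.create_dataset(f"lowpass_{axes[a]}",
                                 data=coeffs.lowpass[a].astype(np.float32))


def read_framelet_coeffs(path: str | Path) -> FrameletCoeffs:
    axes = "xyz"
    with h5py.File(path, "r") as f:
        levels = int(f.attrs["levels"])
        bands = []
        for l0 in range(1, levels + 1):
            lev = {}
            for j in (1, 2):
                lev[j] = np.stack([np.asarray(f[f"L{l0}_B{j}_{axes[a]}"], dtype=np.float64)
                                   for a in range(3)])
            bands.append(lev)
        lowpass = np.stack([np.asarray(f[f"lowpass_{axes[a]}"], dtype=np.float64)
                            for a in range(3)])
    return FrameletCoeffs(bands, lowpass)


def write_metrics_csv(path: str | Path, rows: list[dict]) -> None:
    """Canonical metrics table: columns metric, roi, value."""
    with atomic_path(path) as tmp:
        with open(tmp, "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=["metric", "roi", "value"])
            writer.writeheader()
            for row in rows:
                writer.writerow(row)


def write_manifest(path: str | Path, params: dict) -> None:
    from . import __version__
    payload = dict(params)
    payload["tfct_version"] = __version__
    with atomic_path(path) as tmp:
        tmp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    return json.loads(path.read_text())
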