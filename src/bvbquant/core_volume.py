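"""Volumetric CT container, coordinate conventions, HU windowing and I/O.

Conventions used throughout the package
---------------------------------------
* Voxel arrays are indexed ``data[z, y, x]`` with ``z`` the slice axis.
* ``spacing`` is the per-axis voxel size in mm, ordered ``(z, y, x)``.
* World coordinates are ``(x, y, z)`` positions in mm.  The mapping is the
  axis-aligned affine ``world = origin + index * spacing`` (no rotation);
  phantoms and reformations are generated in this frame.
* Hounsfield units (HU): air is about -1000, water 0, soft tissue 30-80.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "FormatError",
    "VoxelVolume",
    "WindowSetting",
    "Centerline",
    "LUNG_WINDOW",
    "DEFAULT_FILL_HU",
    "read_volume",
    "write_volume",
    "apply_window",
    "sample_trilinear",
]

#: HU value used to fill samples taken outside the volume (air).
DEFAULT_FILL_HU = -1024.0


class FormatError(ValueError):
    """Raised for malformed volume files or invalid geometry metadata."""


@dataclass(frozen=True)
class WindowSetting:
    """CT display window with ``center`` and ``width`` in HU."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.width):
            raise ValueError("window center/width must be finite")
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


#: Default lung window (center -600 HU, width 1500 HU).
LUNG_WINDOW = WindowSetting(center=-600.0, width=1500.0)


@dataclass
class VoxelVolume:
    """A 3D scalar field in Hounsfield units with anisotropic spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU values, finite.
    spacing : tuple of float
        Voxel size in mm, ordered (z, y, x); all components > 0.
    origin : tuple of float
        World (x, y, z) coordinate in mm of voxel index (0, 0, 0).
    ground_truth : dict, optional
        Machine-readable phantom ground truth carried alongside the image.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume data contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be 3 positive components, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices ``(z, y, x)`` to world ``(x, y, z)`` mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        sz, sy, sx = self.spacing
        ox, oy, oz = self.origin
        out = np.column_stack(
            [ox + idx[:, 2] * sx, oy + idx[:, 1] * sy, oz + idx[:, 0] * sz]
        )
        return out[0] if np.asarray(indices).ndim == 1 else out

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world ``(x, y, z)`` mm to fractional voxel indices ``(z, y, x)``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        sz, sy, sx = self.spacing
        ox, oy, oz = self.origin
        out = np.column_stack(
            [(pts[:, 2] - oz) / sz, (pts[:, 1] - oy) / sy, (pts[:, 0] - ox) / sx]
        )
        return out[0] if np.asarray(points).ndim == 1 else out

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box (lo_xyz, hi_xyz) spanned by voxel centers."""
        nz, ny, nx = self.shape
        lo = self.voxel_to_world(np.array([0.0, 0.0, 0.0]))
        hi = self.voxel_to_world(np.array([nz - 1.0, ny - 1.0, nx - 1.0]))
        return np.minimum(lo, hi), np.maximum(lo, hi)


@dataclass
class Centerline:
    """Ordered 3D polyline in world mm defining a reformation path.

    ``points`` has shape (n, 3) in (x, y, z) order, proximal to distal.
    ``arc_length`` is the cumulative length in mm at each point; by default it
    is the cumulative chord length of the polyline, but a caller resampling a
    continuous curve may supply the curve's own arc-length parameter.
    """

    points: np.ndarray
    arc_length: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must have shape (n, 3)")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive centerline points must be distinct")
        if self.arc_length is None:
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arc_length = np.asarray(self.arc_length, dtype=np.float64)
            if self.arc_length.shape != (len(self.points),):
                raise ValueError("arc_length must have one entry per point")
            if np.any(np.diff(self.arc_length) <= 0):
                raise ValueError("arc_length must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arc_length[-1] - self.arc_length[0])

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "") -> "Centerline":
        """Read a centerline from CSV with columns ``x_mm,y_mm,z_mm``."""
        import pandas as pd

        df = pd.read_csv(path)
        missing = {"x_mm", "y_mm", "z_mm"} - set(df.columns)
        if missing:
            raise FormatError(f"centerline CSV missing columns {sorted(missing)}")
        return cls(df[["x_mm", "y_mm", "z_mm"]].to_numpy(), name=name)

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        pd.DataFrame(self.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            path, index=False
        )
        return Path(path)


def _sidecar_path(path: Path) -> Path:
    base = path.name
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            return path.with_name(base[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI plus a JSON sidecar.

    The sidecar records spacing, origin, a SHA-256 checksum of the voxel data
    and any phantom ground truth, so a reformation or measurement run can be
    traced back to the exact image it consumed.
    """
    path = Path(path)
    if not np.all(np.isfinite(vol.data)):
        raise FormatError("refusing to write volume with non-finite voxels")
    sz, sy, sx = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = vol.origin
    # NIfTI array axes are (x, y, z); our array is (z, y, x).
    img = nib.Nifti1Image(np.ascontiguousarray(vol.data.T), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))
    checksum = hashlib.sha256(np.ascontiguousarray(vol.data).tobytes()).hexdigest()
    sidecar = {
        "spacing_mm": list(vol.spacing),
        "origin_mm": list(vol.origin),
        "hu_calibrated": True,
        "sha256": checksum,
    }
    if vol.ground_truth is not None:
        sidecar["ground_truth"] = vol.ground_truth
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI volume (with optional JSON sidecar) into a :class:`VoxelVolume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if len(zooms) != 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"non-positive or missing voxel spacing in header: {zooms}")
    sx, sy, sz = (float(z) for z in zooms)
    origin = tuple(float(v) for v in img.affine[:3, 3])
    data = np.asanyarray(img.dataobj).astype(np.float64).T  # (x,y,z) -> (z,y,x)
    ground_truth = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        ground_truth = meta.get("ground_truth")
        if "origin_mm" in meta:
            origin = tuple(float(v) for v in meta["origin_mm"])
        if "spacing_mm" in meta:
            ssz, ssy, ssx = (float(v) for v in meta["spacing_mm"])
            if min(ssz, ssy, ssx) <= 0:
                raise FormatError(f"non-positive spacing in sidecar: {meta['spacing_mm']}")
            sz, sy, sx = ssz, ssy, ssx
    return VoxelVolume(data, (sz, sy, sx), origin, ground_truth=ground_truth)


def apply_window(vol: VoxelVolume | np.ndarray, w: WindowSetting = LUNG_WINDOW) -> np.ndarray:
    """Map HU values to display intensities in [0, 1].

    ``v`` maps to ``clip((v - (center - width/2)) / width, 0, 1)``; the map is
    monotone non-decreasing, 0.5 at the window center.
    """
    data = vol.data if isinstance(vol, VoxelVolume) else np.asarray(vol, dtype=float)
    lo = w.center - w.width / 2.0
    return np.clip((data - lo) / w.width, 0.0, 1.0)


def sample_trilinear(
    vol: VoxelVolume,
    points: np.ndarray,
    fill_value: float = DEFAULT_FILL_HU,
    out_of_bounds: str = "fill",
) -> np.ndarray:
    """Trilinearly interpolate HU at world ``(x, y, z)`` points.

    Exact at voxel centers and for affine HU fields; bounded by the local
    voxel min/max.  Points outside the voxel-center bounding box get
    ``fill_value`` (``out_of_bounds="fill"``) or raise (``"error"``).
    """
    if out_of_bounds not in ("fill", "error"):
        raise ValueError("out_of_bounds must be 'fill' or 'error'")
    single = np.asarray(points).ndim == 1
    idx = np.atleast_2d(vol.world_to_voxel(points))
    shape = np.array(vol.shape, dtype=float)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    if out_of_bounds == "error" and not np.all(inside):
        raise ValueError("sample point outside volume bounding box")
    vals = map_coordinates(
        vol.data, idx.T, order=1, mode="constant", cval=fill_value
    )
    vals = np.where(inside, vals, fill_value)
    return float(vals[0]) if single else vals
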