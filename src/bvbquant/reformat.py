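"""Oblique multiplanar reconstruction (MPR) and curved planar reformation (CPR).

MPR resamples the HU volume onto an arbitrary oblique plane; CPR resamples it
onto a stack of planes perpendicular to a (smoothed) centerline so that a
tortuous bronchus or vessel is seen in true cross-section at every arc-length
position.  In-plane frames along the path are rotation-minimizing (double
reflection), which avoids torsion-induced twisting of the cross-section
stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .core_volume import (
    DEFAULT_FILL_HU,
    Centerline,
    VoxelVolume,
    sample_trilinear,
)

__all__ = [
    "ObliquePlane",
    "CrossSection",
    "resample_plane",
    "smooth_centerline",
    "curved_planar_reformation",
]


@dataclass
class ObliquePlane:
    """A finite oblique sampling plane.

    ``u_axis`` and ``v_axis`` are orthonormal in-plane directions; the plane
    normal is their cross product.  ``extent`` is (u-extent, v-extent) in mm.
    """

    center: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    extent: tuple[float, float] = (20.0, 20.0)
    pixel_size: float = 0.31

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.u_axis = np.asarray(self.u_axis, dtype=float)
        self.v_axis = np.asarray(self.v_axis, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for name, ax in (("u_axis", self.u_axis), ("v_axis", self.v_axis)):
            if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
        if abs(float(np.dot(self.u_axis, self.v_axis))) > 1e-9:
            raise ValueError("u_axis and v_axis must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_axis, self.v_axis)


@dataclass
class CrossSection:
    """A 2D HU image resampled from the volume on an oblique plane.

    ``image[i, j]`` sits at world position
    ``center + (i - ci) * pixel_size * u + (j - cj) * pixel_size * v``
    with (ci, cj) the image center.  ``arc_position`` is set for CPR stacks.
    """

    image: np.ndarray
    pixel_size: float
    center_world: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    arc_position: float | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("cross-section image must be finite")

    @property
    def center_px(self) -> tuple[float, float]:
        return ((self.image.shape[0] - 1) / 2.0, (self.image.shape[1] - 1) / 2.0)

    def pixel_to_world(self, ij: np.ndarray) -> np.ndarray:
        ci, cj = self.center_px
        ij = np.atleast_2d(np.asarray(ij, dtype=float))
        out = (
            self.center_world
            + (ij[:, [0]] - ci) * self.pixel_size * self.u_axis
            + (ij[:, [1]] - cj) * self.pixel_size * self.v_axis
        )
        return out[0] if np.asarray(ij).ndim == 1 else out


def resample_plane(
    vol: VoxelVolume, plane: ObliquePlane, fill_value: float = DEFAULT_FILL_HU
) -> CrossSection:
    """Trilinearly resample the volume onto an oblique plane."""
    nu = max(2, int(round(plane.extent[0] / plane.pixel_size)) + 1)
    nv = max(2, int(round(plane.extent[1] / plane.pixel_size)) + 1)
    ci, cj = (nu - 1) / 2.0, (nv - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    pts = (
        plane.center
        + (ii - ci)[..., None] * plane.pixel_size * plane.u_axis
        + (jj - cj)[..., None] * plane.pixel_size * plane.v_axis
    )
    vals = sample_trilinear(vol, pts.reshape(-1, 3), fill_value=fill_value)
    return CrossSection(
        image=vals.reshape(nu, nv),
        pixel_size=plane.pixel_size,
        center_world=plane.center.copy(),
        normal=plane.normal,
        u_axis=plane.u_axis.copy(),
        v_axis=plane.v_axis.copy(),
    )


def _spline_resample(points: np.ndarray, step: float, dense_factor: int = 64):
    """Arc-length-uniform resampling of an interpolating cubic spline.

    Returns (resampled points, their arc positions along the continuous
    curve, dense polyline for deviation measurement).
    """
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    )
    spline = CubicSpline(chord, points, axis=0)
    n_dense = max(len(points) * dense_factor, 256)
    t_dense = np.linspace(chord[0], chord[-1], n_dense)
    dense = spline(t_dense)
    s_dense = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
    )
    total = s_dense[-1]
    n_out = max(2, int(np.floor(total / step)) + 1)
    s_out = np.arange(n_out) * step
    s_out[-1] = min(s_out[-1], total)
    out = np.column_stack(
        [np.interp(s_out, s_dense, dense[:, k]) for k in range(3)]
    )
    # always keep the true endpoint
    if total - s_out[-1] > 1e-9:
        out = np.vstack([out, dense[-1]])
        s_out = np.append(s_out, total)
    else:
        out[-1] = dense[-1]
    out[0] = points[0]
    return out, s_out, dense


def smooth_centerline(raw: Centerline, spacing_step: float = 0.5) -> Centerline:
    """Resample a hand-drawn centerline at uniform arc-length steps.

    Fits an interpolating cubic spline through the raw points, re-parameterises
    it by arc length, and samples every ``spacing_step`` mm, preserving both
    endpoints.  The returned centerline's ``arc_length`` is the position along
    the continuous curve; the maximum deviation from the raw polyline is
    stored on the result as ``deviation_mm``.
    """
    if len(raw.points) < 4:
        raise ValueError("centerline smoothing needs at least 4 points")
    if spacing_step <= 0:
        raise ValueError("spacing_step must be > 0")
    # reject (near-)duplicated points: the chord parameterisation degenerates
    seg = np.linalg.norm(np.diff(raw.points, axis=0), axis=1)
    if np.any(seg < 1e-9):
        raise ValueError("centerline contains duplicated consecutive points")
    out, s_out, dense = _spline_resample(raw.points, spacing_step)
    # deviation of the smoothed curve from the raw polyline
    dev = _max_polyline_deviation(dense, raw.points)
    cl = Centerline(out, arc_length=s_out, name=raw.name)
    cl.deviation_mm = dev  # type: ignore[attr-defined]
    return cl


def _max_polyline_deviation(samples: np.ndarray, poly: np.ndarray) -> float:
    """Max distance from each sample point to the polyline ``poly``."""
    a = poly[:-1]
    ab = poly[1:] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    best = np.full(len(samples), np.inf)
    for k in range(len(a)):
        ap = samples - a[k]
        t = np.clip(ap @ ab[k] / denom[k], 0.0, 1.0)
        d = np.linalg.norm(ap - t[:, None] * ab[k], axis=1)
        best = np.minimum(best, d)
    return float(best.max())


def _rotation_minimizing_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tangents (central differences) and double-reflection RMF normals."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # initial in-plane axis: any unit vector perpendicular to t0
    t0 = tangents[0]
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, t0)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(t0, helper)
    u /= np.linalg.norm(u)
    normals = np.empty_like(tangents)
    normals[0] = u
    for i in range(len(points) - 1):
        # double reflection (Wang et al. 2008)
        v1 = points[i + 1] - points[i]
        c1 = float(v1 @ v1)
        if c1 == 0:
            normals[i + 1] = normals[i]
            continue
        rL = normals[i] - (2.0 / c1) * (v1 @ normals[i]) * v1
        tL = tangents[i] - (2.0 / c1) * (v1 @ tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = float(v2 @ v2)
        if c2 == 0:
            normals[i + 1] = rL
        else:
            normals[i + 1] = rL - (2.0 / c2) * (v2 @ rL) * v2
        normals[i + 1] /= np.linalg.norm(normals[i + 1])
    return tangents, normals


def curved_planar_reformation(
    vol: VoxelVolume,
    cl: Centerline,
    width: float = 20.0,
    pixel_size: float | None = None,
    step: float | None = None,
    fill_value: float = DEFAULT_FILL_HU,
) -> list[CrossSection]:
    """Resample cross-sections perpendicular to a centerline.

    One section is produced per arc-length ``step`` (default: the smaller
    in-plane voxel size); each section is ``width`` x ``width`` mm around the
    path with pixels of ``pixel_size`` mm (default: step).  Raises if the
    path comes within ``width / 2`` of the volume boundary, where a
    cross-section could no longer be filled from real data.
    """
    sz, sy, sx = vol.spacing
    if step is None:
        step = min(sy, sx)
    if pixel_size is None:
        pixel_size = step
    lo, hi = vol.world_bounds()
    margin = width / 2.0
    pts = cl.points
    if np.any(pts < lo + margin - 1e-9) or np.any(pts > hi - margin + 1e-9):
        raise ValueError("centerline too close to the volume boundary for CPR")
    if len(pts) >= 4:
        samples, arc, _ = _spline_resample(pts, step)
    else:
        # short polylines: uniform linear resampling
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        n_out = max(2, int(np.floor(chord[-1] / step)) + 1)
        arc = np.linspace(0.0, chord[-1], n_out)
        samples = np.column_stack(
            [np.interp(arc, chord, pts[:, k]) for k in range(3)]
        )
    tangents, normals = _rotation_minimizing_frames(samples)
    sections = []
    for k in range(len(samples)):
        u = normals[k]
        v = np.cross(tangents[k], u)
        v /= np.linalg.norm(v)
        plane = ObliquePlane(
            center=samples[k],
            u_axis=u,
            v_axis=v,
            extent=(width, width),
            pixel_size=pixel_size,
        )
        sec = resample_plane(vol, plane, fill_value=fill_value)
        sec.arc_position = float(arc[k])
        sections.append(sec)
    return sections
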