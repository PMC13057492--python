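"""Bronchovascular-bundle morphometrics on CT cross-sections.

Implements the three quantitative parameters and the rule-based sign used
for pneumoconiosis staging:

* WT/D — bronchial wall thickness over lumen inner diameter at the narrowest
  cross-section, measured by full-width-half-maximum (FWHM) ray casting;
* AVI — angle variation index: absolute deviation of the 3D vascular
  bifurcation angle (between branch principal directions) from the healthy
  reference of 110 degrees;
* FD — box-counting fractal dimension of the peribronchial soft-tissue
  pattern in a 2 mm annulus outside the airway wall;
* cuffing sign — a peribronchial soft-tissue ring (> 30 HU) covering more
  than half of the circumference, at least 2 mm thick, persisting over more
  than 3 consecutive slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import label

from .core_volume import Centerline
from .reformat import CrossSection

__all__ = [
    "AVI_REFERENCE_DEG",
    "MeasurementError",
    "AirwayMeasurement",
    "BifurcationGeometry",
    "FractalResult",
    "CuffingResult",
    "measure_wall",
    "find_narrowest_section",
    "branch_direction",
    "bifurcation_angle",
    "compute_avi",
    "peribronchial_roi",
    "box_counting_fd",
    "detect_cuffing",
]

#: Healthy-population reference for the pulmonary-artery bifurcation angle.
AVI_REFERENCE_DEG = 110.0

#: HU below which a pixel is treated as air (lumen candidate).
_AIR_HU = -500.0


class MeasurementError(RuntimeError):
    """A morphometric measurement could not be completed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class AirwayMeasurement:
    """FWHM wall measurement of one airway cross-section (all lengths mm)."""

    inner_diameter_d: float
    wall_thickness_wt: float
    arc_position: float | None = None
    center_px: tuple[float, float] | None = None
    rays_total: int = 0
    rays_valid: int = 0
    inner_radii: np.ndarray | None = field(default=None, repr=False)
    outer_radii: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.inner_diameter_d <= 0 or self.wall_thickness_wt <= 0:
            raise ValueError("diameter and wall thickness must be > 0")

    @property
    def wt_d_ratio(self) -> float:
        return self.wall_thickness_wt / self.inner_diameter_d


@dataclass(frozen=True)
class BifurcationGeometry:
    """Measured 3D bifurcation angle and its deviation from the reference."""

    daughter_angle_deg: float
    reference_angle_deg: float = AVI_REFERENCE_DEG

    def __post_init__(self) -> None:
        if not 0.0 <= self.daughter_angle_deg <= 180.0:
            raise ValueError("daughter_angle_deg must be in [0, 180]")

    @property
    def avi_deg(self) -> float:
        return abs(self.daughter_angle_deg - self.reference_angle_deg)


@dataclass
class FractalResult:
    """Box-counting result: dimension, the counts behind it and fit quality."""

    fd: float
    box_sizes_mm: np.ndarray
    box_counts: np.ndarray
    fit_r2: float


@dataclass
class CuffingResult:
    """Outcome of the rule-based cuffing-sign detector.

    ``coverage_fraction`` is the largest qualifying angular coverage among the
    sections of the best consecutive run; ``consecutive_slices`` is that run's
    length.  ``positive`` requires coverage > 0.5, thickness >= 2 mm and a run
    of strictly more than 3 sections (all inequalities read literally).
    """

    positive: bool
    coverage_fraction: float
    cuff_thickness_mm: float
    consecutive_slices: int
    per_section_coverage: np.ndarray | None = field(default=None, repr=False)


def _bilinear(image: np.ndarray, ij: np.ndarray) -> np.ndarray:
    return map_coordinates(image, ij.T, order=1, mode="nearest")


def _lumen_centroid(section: CrossSection, lumen_seed) -> np.ndarray:
    """Centroid (pixel coords) of the air region containing the seed."""
    img = section.image
    if lumen_seed is None:
        lumen_seed = section.center_px
    si, sj = int(round(lumen_seed[0])), int(round(lumen_seed[1]))
    if not (0 <= si < img.shape[0] and 0 <= sj < img.shape[1]):
        raise MeasurementError("lumen seed outside the image")
    if img[si, sj] >= _AIR_HU:
        raise MeasurementError(
            f"lumen seed not in an air-density region (HU={img[si, sj]:.0f})"
        )
    labels = label(img < _AIR_HU, connectivity=1)
    region = labels == labels[si, sj]
    idx = np.argwhere(region)
    return idx.mean(axis=0)


def _ray_profile_edges(
    profile: np.ndarray,
    r_step: float,
    lumen_val: float,
    wall_plateau: float,
) -> tuple[float, float] | None:
    """FWHM inner/outer edge radii along one outward ray, or None.

    The profile runs from the lumen center outward: an air plateau, a rise
    through the wall, then a fall toward parenchyma.  The inner edge is the
    half-maximum crossing between the lumen plateau and the wall plateau, the
    outer edge the half-maximum crossing between the wall plateau and the
    parenchyma level beyond it.  The wall plateau is estimated globally
    across rays (a thin wall never reaches its plateau on every single ray,
    and using the attenuated per-ray peak would bias both edges outward of
    their half-maximum positions).  Crossings get subpixel linear
    interpolation.
    """
    k_peak = int(np.argmax(profile))
    peak_val = float(profile[k_peak])
    if k_peak < 2 or peak_val - lumen_val < 100.0:
        return None  # no wall signal on this ray
    th_in = 0.5 * (lumen_val + wall_plateau)
    above = np.nonzero(profile[: k_peak + 1] >= th_in)[0]
    if len(above) == 0 or above[0] == 0:
        return None
    k = above[0]
    frac = (th_in - profile[k - 1]) / (profile[k] - profile[k - 1])
    r_inner = (k - 1 + frac) * r_step

    tail = profile[k_peak:]
    parench_val = float(np.median(tail[-max(3, len(tail) // 5):]))
    if wall_plateau - parench_val < 100.0:
        return None  # wall never falls off: open wall / touching structure
    th_out = 0.5 * (wall_plateau + parench_val)
    below = np.nonzero(tail <= th_out)[0]
    if len(below) == 0 or below[0] == 0:
        return None
    k2 = below[0]
    frac2 = (profile[k_peak + k2 - 1] - th_out) / (
        profile[k_peak + k2 - 1] - profile[k_peak + k2]
    )
    r_outer = (k_peak + k2 - 1 + frac2) * r_step
    if r_outer <= r_inner:
        return None
    return r_inner, r_outer


def measure_wall(
    section: CrossSection,
    lumen_seed=None,
    n_rays: int = 72,
    max_invalid_fraction: float = 0.25,
) -> AirwayMeasurement:
    """Measure lumen inner diameter D and wall thickness WT by FWHM ray casting.

    Casts ``n_rays`` equally spaced rays outward from the lumen centroid and
    localises the inner and outer wall edges on each by the half-maximum
    convention. D is twice the mean inner-edge radius; WT the mean (outer -
    inner) distance over valid rays.  Fails when more than
    ``max_invalid_fraction`` of rays find no closed wall.
    """
    center = _lumen_centroid(section, lumen_seed)
    img = section.image
    ps = section.pixel_size
    r_step_px = 0.25
    r_max_px = min(
        center[0], center[1], img.shape[0] - 1 - center[0], img.shape[1] - 1 - center[1]
    )
    if r_max_px < 4:
        raise MeasurementError("lumen centroid too close to the image border")
    radii_px = np.arange(0.0, r_max_px, r_step_px)
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    profiles = []
    for th in angles:
        di, dj = np.cos(th), np.sin(th)
        coords = np.column_stack([center[0] + radii_px * di, center[1] + radii_px * dj])
        profiles.append(_bilinear(img, coords))
    # global plateau estimates shared by all rays
    lumen_val = float(np.median([p[:2].mean() for p in profiles]))
    peaks = np.array([p.max() for p in profiles])
    strong = peaks[peaks - lumen_val > 100.0]
    if len(strong) == 0:
        raise MeasurementError("no wall signal on any ray")
    wall_plateau = float(np.percentile(strong, 95))
    inner, outer = [], []
    n_invalid = 0
    for profile in profiles:
        edges = _ray_profile_edges(profile, r_step_px * ps, lumen_val, wall_plateau)
        if edges is None:
            n_invalid += 1
            inner.append(np.nan)
            outer.append(np.nan)
        else:
            inner.append(edges[0])
            outer.append(edges[1])
    if n_invalid > max_invalid_fraction * n_rays:
        raise MeasurementError(
            f"no closed wall on {n_invalid}/{n_rays} rays",
            diagnostics={"n_invalid": n_invalid, "n_rays": n_rays},
        )
    inner = np.asarray(inner)
    outer = np.asarray(outer)
    valid = ~np.isnan(inner)
    d = 2.0 * float(np.nanmean(inner))
    wt = float(np.nanmean(outer - inner))
    return AirwayMeasurement(
        inner_diameter_d=d,
        wall_thickness_wt=wt,
        arc_position=section.arc_position,
        center_px=(float(center[0]), float(center[1])),
        rays_total=n_rays,
        rays_valid=int(valid.sum()),
        inner_radii=inner,
        outer_radii=outer,
    )


def find_narrowest_section(
    stack: list[CrossSection], lumen_seed=None, n_rays: int = 72
) -> tuple[CrossSection, AirwayMeasurement]:
    """Pick the cross-section with the smallest lumen inner diameter.

    Ties go to the smallest arc position (stack order).  Sections where the
    wall measurement fails are skipped; at least 3 measurable sections are
    required.
    """
    if len(stack) < 3:
        raise ValueError("need at least 3 cross-sections")
    best: tuple[CrossSection, AirwayMeasurement] | None = None
    n_ok = 0
    for sec in stack:
        try:
            m = measure_wall(sec, lumen_seed=lumen_seed, n_rays=n_rays)
        except MeasurementError:
            continue
        n_ok += 1
        if best is None or m.inner_diameter_d < best[1].inner_diameter_d - 1e-12:
            best = (sec, m)
    if best is None or n_ok < 3:
        raise MeasurementError(f"only {n_ok} of {len(stack)} sections measurable")
    return best


def branch_direction(
    cl: Centerline, from_vertex, length: float = 10.0
) -> np.ndarray:
    """Principal direction of a branch near a vertex, oriented away from it.

    Takes the centerline points within ``length`` mm of the vertex and returns
    the dominant eigenvector of their scatter, signed so it points from the
    vertex toward the branch (unit norm).
    """
    vertex = np.asarray(from_vertex, dtype=float)
    pts = cl.points[np.linalg.norm(cl.points - vertex, axis=1) <= length]
    if len(pts) < 3:
        raise ValueError("fewer than 3 centerline points within reach of the vertex")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 1e-12:
        raise ValueError("degenerate point scatter (coincident points)")
    direction = v[:, -1]
    away = pts.mean(axis=0) - vertex
    if np.dot(direction, away) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


def bifurcation_angle(d1, d2) -> float:
    """3D angle in degrees between two branch direction vectors."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n1, n2 = np.linalg.norm(d1), np.linalg.norm(d2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length direction vector")
    cosang = np.clip(np.dot(d1, d2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def compute_avi(angle_deg: float, reference_deg: float = AVI_REFERENCE_DEG) -> float:
    """Angle variation index: absolute deviation from the healthy reference."""
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("angle must be in [0, 180] degrees")
    return abs(angle_deg - reference_deg)


def peribronchial_roi(
    section: CrossSection, wall: AirwayMeasurement, band_mm: float = 2.0
) -> np.ndarray:
    """Annular mask from the outer wall edge outward by ``band_mm``.

    Returns a boolean mask on the section's pixel grid.  Raises if the outer
    annulus would leave the image, where the texture would be truncated.
    """
    if band_mm < 0:
        raise ValueError("band_mm must be >= 0")
    ci, cj = wall.center_px if wall.center_px is not None else section.center_px
    ps = section.pixel_size
    r_outer = wall.inner_diameter_d / 2.0 + wall.wall_thickness_wt
    r_hi = r_outer + band_mm
    ni, nj = section.image.shape
    lim = min(ci, cj, ni - 1 - ci, nj - 1 - cj) * ps
    if r_hi > lim + 1e-9:
        raise MeasurementError("peribronchial annulus exits the image bounds")
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    r = np.hypot(ii - ci, jj - cj) * ps
    return (r >= r_outer) & (r < r_hi)


def box_counting_fd(
    mask_or_image: np.ndarray,
    pixel_size: float = 1.0,
    threshold: float | None = None,
    roi_mask: np.ndarray | None = None,
) -> FractalResult:
    """Box-counting fractal dimension of a 2D set.

    Scalar input is binarised at ``threshold`` HU (boolean input is used
    as-is); ``roi_mask`` optionally restricts the foreground.  Occupied boxes
    are counted on a geometric ladder of box sizes, preferring sizes that
    divide the grid evenly (a grid of partial boxes at the image border
    inflates counts and systematically flattens the scaling law); at each
    scale the count is minimised over 4 grid offsets, the natural estimator
    of the covering number.  FD is minus the slope of the least-squares fit
    of log(count) against log(box size).  Needs at least a 27 x 27 grid and
    4 scales.
    """
    arr = np.asarray(mask_or_image)
    if arr.ndim != 2:
        raise ValueError("input must be 2D")
    if min(arr.shape) < 27:
        raise ValueError("ROI must be at least 27 x 27 pixels")
    if arr.dtype == bool:
        fg = arr
    else:
        if threshold is None:
            raise ValueError("scalar input requires a binarisation threshold")
        fg = arr > threshold
    if roi_mask is not None:
        fg = fg & roi_mask
    if not fg.any():
        raise MeasurementError("empty foreground: fractal dimension undefined")

    n = min(fg.shape)
    divisors = [s for s in range(1, n // 3 + 1) if n % s == 0]
    if len(divisors) >= 4:
        sizes = divisors
    else:  # irregular grid size: fall back to a dyadic ladder with padding
        sizes = []
        s = 1
        while s <= n // 4:
            sizes.append(s)
            s *= 2
    if len(sizes) > 8:  # thin a dense divisor ladder geometrically
        keep = np.unique(
            np.round(np.geomspace(1, len(sizes), 8)).astype(int) - 1
        )
        sizes = [sizes[i] for i in keep]
    if len(sizes) < 4:
        raise ValueError("fewer than 4 box-count scales available")

    counts = []
    for s in sizes:
        if s == 1:
            counts.append(float(fg.sum()))
            continue
        offs = [(0, 0), (s // 2, 0), (0, s // 2), (s // 2, s // 2)]
        c_off = []
        for oi, oj in offs:
            pi = (-(fg.shape[0] + oi) % s, -(fg.shape[1] + oj) % s)
            padded = np.pad(fg, ((oi, pi[0]), (oj, pi[1])), constant_values=False)
            blocks = padded.reshape(
                padded.shape[0] // s, s, padded.shape[1] // s, s
            ).any(axis=(1, 3))
            c_off.append(float(blocks.sum()))
        counts.append(float(np.min(c_off)))
    sizes_mm = np.asarray(sizes, dtype=float) * pixel_size
    counts = np.asarray(counts)
    x = np.log(sizes_mm)
    y = np.log(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return FractalResult(
        fd=float(-slope), box_sizes_mm=sizes_mm, box_counts=counts, fit_r2=r2
    )


def _section_cuff_profile(
    section: CrossSection,
    wall: AirwayMeasurement,
    hu_threshold: float,
    min_thickness_mm: float,
    n_rays: int = 360,
) -> tuple[float, float]:
    """(qualifying angular fraction, median qualifying run thickness in mm).

    Sweeps one-degree rays outward from the outer wall edge; a ray qualifies
    if the contiguous run of samples above ``hu_threshold`` starting at the
    outer edge extends at least ``min_thickness_mm``.
    """
    img = section.image
    ps = section.pixel_size
    ci, cj = wall.center_px if wall.center_px is not None else section.center_px
    r0 = (wall.inner_diameter_d / 2.0 + wall.wall_thickness_wt) / ps  # px
    r_step = 0.25
    r_max = min(ci, cj, img.shape[0] - 1 - ci, img.shape[1] - 1 - cj)
    if r0 >= r_max:
        return 0.0, 0.0
    radii = np.arange(r0 + r_step, r_max, r_step)
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    qualifying = 0
    run_lengths = []
    for th in angles:
        coords = np.column_stack(
            [ci + radii * np.cos(th), cj + radii * np.sin(th)]
        )
        profile = _bilinear(img, coords)
        above = profile > hu_threshold
        if not above[0]:
            continue
        k_end = np.argmin(above) if not above.all() else len(above)
        run_mm = k_end * r_step * ps
        if run_mm >= min_thickness_mm:
            qualifying += 1
            run_lengths.append(run_mm)
    thickness = float(np.median(run_lengths)) if run_lengths else 0.0
    return qualifying / n_rays, thickness


def detect_cuffing(
    stack: list[CrossSection],
    walls: list[AirwayMeasurement | None],
    hu_threshold: float = 30.0,
    min_coverage: float = 0.5,
    min_thickness_mm: float = 2.0,
    min_slices: int = 3,
    n_rays: int = 360,
) -> CuffingResult:
    """Rule-based cuffing-sign detection on a stack of cross-sections.

    A section qualifies when soft-tissue density (> ``hu_threshold`` HU)
    outside the airway wall covers more than ``min_coverage`` of the
    circumference with radial thickness at least ``min_thickness_mm``; the
    sign is positive when strictly more than ``min_slices`` consecutive
    sections qualify.  Sections with a missing wall measurement count as
    non-qualifying.
    """
    if len(stack) < min_slices + 1:
        raise ValueError(f"need at least {min_slices + 1} sections")
    coverages = np.zeros(len(stack))
    thicknesses = np.zeros(len(stack))
    for k, (sec, wall) in enumerate(zip(stack, walls)):
        if wall is None:
            continue
        cov, thick = _section_cuff_profile(
            sec, wall, hu_threshold, min_thickness_mm, n_rays=n_rays
        )
        coverages[k] = cov
        thicknesses[k] = thick
    qualifies = coverages > min_coverage

    best_len, best_start = 0, 0
    k = 0
    while k < len(stack):
        if qualifies[k]:
            j = k
            while j + 1 < len(stack) and qualifies[j + 1]:
                j += 1
            if j - k + 1 > best_len:
                best_len, best_start = j - k + 1, k
            k = j + 1
        else:
            k += 1
    if best_len > 0:
        sl = slice(best_start, best_start + best_len)
        coverage = float(coverages[sl].max())
        thickness = float(np.median(thicknesses[sl]))
    else:
        coverage = float(coverages.max()) if len(stack) else 0.0
        thickness = 0.0
    positive = best_len > min_slices
    return CuffingResult(
        positive=bool(positive),
        coverage_fraction=coverage,
        cuff_thickness_mm=thickness,
        consecutive_slices=int(best_len),
        per_section_coverage=coverages,
    )
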