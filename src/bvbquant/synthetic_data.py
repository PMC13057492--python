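"""Digital CT phantoms and per-patient cohort simulation.

Every measurement stage in this package is validated against objects whose
ground truth is known by construction:

* airway phantoms — a cylindrical air lumen with a soft-tissue wall inside
  lung-density parenchyma, optionally wearing a partial peribronchial cuff,
  with seeded Gaussian HU noise at a realistic CT noise level;
* bifurcation phantoms — straight tubes meeting at a vertex with an exactly
  known 3D angle between the daughter branches, plus their centerlines;
* planar fractal textures with analytically known box-counting dimension;
* cohorts of per-patient morphometric values (WT/D, AVI, FD, cuffing sign)
  drawn stage-by-stage from stated means/SDs, with auxiliary clinical
  variables given target correlations through a Gaussian copula.

Phantom voxels are rasterized with subvoxel supersampling so that edge
voxels carry realistic partial-volume values; this is what makes subpixel
(half-maximum) edge localisation meaningful on the phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_volume import Centerline, VoxelVolume

__all__ = [
    "HU_LUMEN",
    "HU_WALL",
    "HU_PARENCHYMA",
    "HU_VESSEL",
    "HU_CUFF",
    "DEFAULT_SPACING_MM",
    "DEFAULT_NOISE_SD_HU",
    "CuffSpec",
    "AirwayPhantomSpec",
    "BifurcationPhantomSpec",
    "FractalTextureSpec",
    "CohortSpec",
    "make_airway_phantom",
    "make_bifurcation_phantom",
    "make_fractal_texture",
    "sierpinski_carpet",
    "correlated_normal",
    "simulate_cohort",
]

# Default HU palette: air lumen, bronchial wall, aerated parenchyma, vessel,
# peribronchial cuff.  Chosen to be physically plausible and consistent with
# the >30 HU soft-tissue bound used by the cuffing-sign rule.
HU_LUMEN = -1000.0
HU_WALL = 40.0
HU_PARENCHYMA = -850.0
HU_VESSEL = 60.0
HU_CUFF = 50.0

#: Default isotropic voxel size in mm (thin-slice chest CT reconstruction).
DEFAULT_SPACING_MM = (0.62, 0.62, 0.62)
#: Default image noise SD in HU (typical thin-slice chest CT).
DEFAULT_NOISE_SD_HU = 12.4


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalised")
    return v / n


def _perpendicular(a: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to unit vector ``a``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, a)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    return u / np.linalg.norm(u)


@dataclass(frozen=True)
class CuffSpec:
    """Partial peribronchial soft-tissue ring outside the airway wall.

    ``coverage_fraction`` is realised as an angular sector of the full ring,
    so the ground-truth circumferential coverage is exact; ``n_slices`` is the
    number of consecutive slice-thick bands along the tube axis that carry
    the cuff.
    """

    thickness_mm: float = 3.0
    coverage_fraction: float = 1.0
    hu: float = HU_CUFF
    n_slices: int = 5

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("cuff thickness must be > 0")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in [0, 1]")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")


@dataclass(frozen=True)
class AirwayPhantomSpec:
    """Geometry and HU palette of a straight-airway phantom."""

    lumen_diameter_mm: float = 4.0
    wall_thickness_mm: float = 1.04
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    length_mm: float = 20.0
    lumen_hu: float = HU_LUMEN
    wall_hu: float = HU_WALL
    parenchyma_hu: float = HU_PARENCHYMA
    cuff: CuffSpec | None = None
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_diameter_mm <= 0:
            raise ValueError("lumen_diameter_mm must be > 0")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be > 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be > 0")


@dataclass(frozen=True)
class BifurcationPhantomSpec:
    """Two straight daughter tubes leaving a parent at a known 3D angle."""

    parent_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    daughter_angle_deg: float = 110.0
    branch_radius_mm: float = 2.0
    branch_length_mm: float = 15.0
    branch_hu: float = HU_VESSEL
    parenchyma_hu: float = HU_PARENCHYMA
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.daughter_angle_deg < 180.0:
            raise ValueError("daughter_angle_deg must be in (0, 180)")
        if self.branch_radius_mm <= 0:
            raise ValueError("branch_radius_mm must be > 0")


@dataclass(frozen=True)
class FractalTextureSpec:
    """Planar texture with known box-counting dimension.

    Patterns: ``filled`` (dimension 2), ``sierpinski_carpet`` (dimension
    log 8 / log 3), ``fbm`` (the zero-set contour of a fractional Brownian
    surface with Hurst exponent H, box dimension 2 - H, so H is chosen as
    ``2 - target_fd``).
    """

    pattern: str = "fbm"
    target_fd: float = 1.5
    depth: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("filled", "sierpinski_carpet", "fbm"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "fbm" and not 1.0 < self.target_fd <= 2.0:
            raise ValueError("target_fd must be in (1, 2] for planar textures")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _supersampled_grid(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    factor: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World (x, y, z) coordinate grids for subvoxel sample points."""
    axes = []
    for n, s, o in zip(shape, spacing, origin[::-1]):  # (z,y,x) with origin z,y,x
        sub = (np.arange(n * factor) + 0.5) / factor - 0.5
        axes.append(o + sub * s)
    zz, yy, xx = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    return xx, yy, zz


def _block_mean(a: np.ndarray, f: int) -> np.ndarray:
    nz, ny, nx = (n // f for n in a.shape)
    return a.reshape(nz, f, ny, f, nx, f).mean(axis=(1, 3, 5))


def make_airway_phantom(
    spec: AirwayPhantomSpec,
    spacing: tuple[float, float, float] = DEFAULT_SPACING_MM,
    supersample: int = 3,
) -> VoxelVolume:
    """Rasterize an airway phantom; ground truth rides in ``vol.ground_truth``.

    The tube axis passes through the volume center.  Requires in-plane voxel
    size no coarser than a quarter of the lumen diameter so the lumen is
    adequately sampled.
    """
    sz, sy, sx = spacing
    if max(sy, sx) > spec.lumen_diameter_mm / 4.0:
        raise ValueError(
            f"in-plane spacing {max(sy, sx)} mm too coarse for lumen "
            f"{spec.lumen_diameter_mm} mm (need <= diameter/4)"
        )
    a = _unit(spec.axis)
    r_lumen = spec.lumen_diameter_mm / 2.0
    r_outer = r_lumen + spec.wall_thickness_mm
    cuff = spec.cuff
    radial_extent = r_outer + (cuff.thickness_mm if cuff else 0.0) + 4.0
    half = np.abs(a) * (spec.length_mm / 2.0) + radial_extent
    # shape in (z, y, x); world extent 2*half in (x, y, z)
    shape = tuple(
        int(np.ceil(2 * h / s)) for h, s in zip(half[::-1], (sz, sy, sx))
    )
    origin_xyz = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape[::-1], (sx, sy, sz)))

    f = max(1, int(supersample))
    xx, yy, zz = _supersampled_grid(shape, (sz, sy, sx), origin_xyz, f)
    # displacement from the volume center (tube passes through the origin)
    dx, dy, dz = xx, yy, zz
    t = dx * a[0] + dy * a[1] + dz * a[2]
    rx, ry, rz = dx - t * a[0], dy - t * a[1], dz - t * a[2]
    r = np.sqrt(rx * rx + ry * ry + rz * rz)

    hu = np.full(r.shape, spec.parenchyma_hu)
    if cuff is not None and cuff.coverage_fraction > 0:
        u = _perpendicular(a)
        v = np.cross(a, u)
        ang = np.arctan2(rx * v[0] + ry * v[1] + rz * v[2], rx * u[0] + ry * u[1] + rz * u[2])
        ang = np.mod(ang, 2 * np.pi)
        axis_step = min(sz, sy, sx)
        band = cuff.n_slices * axis_step / 2.0
        in_cuff = (
            (r >= r_outer)
            & (r < r_outer + cuff.thickness_mm)
            & (ang < cuff.coverage_fraction * 2 * np.pi)
            & (np.abs(t) <= band)
        )
        hu[in_cuff] = cuff.hu
    hu[r < r_outer] = spec.wall_hu
    hu[r < r_lumen] = spec.lumen_hu
    data = _block_mean(hu, f)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_hu > 0:
        data = data + rng.normal(0.0, spec.noise_sd_hu, size=data.shape)

    gt = {
        "kind": "airway",
        "lumen_diameter_mm": spec.lumen_diameter_mm,
        "wall_thickness_mm": spec.wall_thickness_mm,
        "wt_d_ratio": spec.wall_thickness_mm / spec.lumen_diameter_mm,
        "axis": list(a),
        "length_mm": spec.length_mm,
        "lumen_hu": spec.lumen_hu,
        "wall_hu": spec.wall_hu,
        "parenchyma_hu": spec.parenchyma_hu,
        "noise_sd_hu": spec.noise_sd_hu,
        "seed": spec.seed,
        "cuff": None
        if cuff is None
        else {
            "thickness_mm": cuff.thickness_mm,
            "coverage_fraction": cuff.coverage_fraction,
            "hu": cuff.hu,
            "n_slices": cuff.n_slices,
        },
    }
    return VoxelVolume(data, (sz, sy, sx), origin_xyz, ground_truth=gt)


def make_bifurcation_phantom(
    spec: BifurcationPhantomSpec,
    spacing: tuple[float, float, float] = DEFAULT_SPACING_MM,
    supersample: int = 2,
) -> tuple[VoxelVolume, dict[str, Centerline]]:
    """Rasterize a bifurcation phantom and emit on-axis branch centerlines.

    The two daughter axes are placed symmetrically about the parent direction
    in a fixed plane, so the analytic 3D angle between them equals
    ``spec.daughter_angle_deg`` exactly; the returned centerlines lie on the
    tube axes (keys ``parent``, ``daughter1``, ``daughter2``).
    """
    p = _unit(spec.parent_direction)
    w = _perpendicular(p)
    half_ang = np.deg2rad(spec.daughter_angle_deg) / 2.0
    d1 = np.cos(half_ang) * p + np.sin(half_ang) * w
    d2 = np.cos(half_ang) * p - np.sin(half_ang) * w
    L = spec.branch_length_mm
    vertex = np.zeros(3)
    segments = [
        (vertex - p * L, vertex),
        (vertex, vertex + d1 * L),
        (vertex, vertex + d2 * L),
    ]

    sz, sy, sx = spacing
    ends = np.array([s for seg in segments for s in seg])
    half = np.max(np.abs(ends), axis=0) + spec.branch_radius_mm + 3.0
    shape = tuple(int(np.ceil(2 * h / s)) for h, s in zip(half[::-1], (sz, sy, sx)))
    origin_xyz = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape[::-1], (sx, sy, sz)))

    f = max(1, int(supersample))
    xx, yy, zz = _supersampled_grid(shape, (sz, sy, sx), origin_xyz, f)
    pts = np.stack([xx, yy, zz], axis=-1)
    dist = np.full(pts.shape[:-1], np.inf)
    for a_pt, b_pt in segments:
        ab = b_pt - a_pt
        denom = float(np.dot(ab, ab))
        ap = pts - a_pt
        tproj = np.clip((ap @ ab) / denom, 0.0, 1.0)
        closest = a_pt + tproj[..., None] * ab
        dist = np.minimum(dist, np.linalg.norm(pts - closest, axis=-1))
    hu = np.where(dist < spec.branch_radius_mm, spec.branch_hu, spec.parenchyma_hu)
    data = _block_mean(hu, f)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_hu > 0:
        data = data + rng.normal(0.0, spec.noise_sd_hu, size=data.shape)

    step = min(sz, sy, sx)
    n_pts = max(2, int(L / step))
    ts = np.linspace(0.0, L, n_pts)
    centerlines = {
        "parent": Centerline((vertex - p * L) + np.outer(ts, p), name="parent"),
        "daughter1": Centerline(vertex + np.outer(ts, d1), name="daughter1"),
        "daughter2": Centerline(vertex + np.outer(ts, d2), name="daughter2"),
    }
    gt = {
        "kind": "bifurcation",
        "daughter_angle_deg": spec.daughter_angle_deg,
        "parent_direction": list(p),
        "daughter1_direction": list(d1),
        "daughter2_direction": list(d2),
        "branch_radius_mm": spec.branch_radius_mm,
        "seed": spec.seed,
    }
    vol = VoxelVolume(data, (sz, sy, sx), origin_xyz, ground_truth=gt)
    return vol, centerlines


def sierpinski_carpet(depth: int, size: int) -> np.ndarray:
    """Boolean depth-``depth`` Sierpinski carpet on a ``size`` x ``size`` grid.

    ``size`` must be a power of 3 with 3**depth <= size; occupancy is exactly
    (8/9)**depth.
    """
    m = int(round(np.log(size) / np.log(3)))
    if 3**m != size:
        raise ValueError(f"size must be a power of 3, got {size}")
    if depth > m:
        raise ValueError(f"depth {depth} too deep for size {size}")
    idx = np.arange(size)
    keep = np.ones((size, size), dtype=bool)
    for level in range(depth):
        digit = (idx // 3 ** (m - 1 - level)) % 3
        keep &= ~((digit[:, None] == 1) & (digit[None, :] == 1))
    return keep


def _fbm_surface(size: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Brownian surface by spectral synthesis (power ~ f^-(2H+2))."""
    fz = np.fft.fftfreq(size)
    fmag = np.sqrt(fz[:, None] ** 2 + fz[None, :] ** 2)
    fmag[0, 0] = np.inf  # kill the DC term
    amplitude = fmag ** (-(hurst + 1.0))
    phase = rng.uniform(0, 2 * np.pi, size=(size, size))
    spectrum = amplitude * np.exp(1j * phase)
    surf = np.real(np.fft.ifft2(spectrum))
    return (surf - surf.mean()) / surf.std()


# Median-level-set box dimension measured on 256 x 256 spectral-synthesis
# surfaces as a function of the Hurst exponent (30 fields per entry).  The
# asymptotic law for a true fractional Brownian level set is 2 - H, but at
# finite grid size the measured dimension sits below it; the generator
# promises the *measured expected* dimension, so it inverts this calibrated
# response instead of the asymptotic formula.
_FBM_HURST_GRID = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
_FBM_MEASURED_FD = np.array(
    [1.6964, 1.6243, 1.5473, 1.4706, 1.3970, 1.3276, 1.2663, 1.2086]
)


def _hurst_for_target_fd(target_fd: float) -> float:
    """Invert the calibrated level-set response (linear extrapolation outside)."""
    fd_asc = _FBM_MEASURED_FD[::-1]
    h_asc = _FBM_HURST_GRID[::-1]
    if target_fd <= fd_asc[0]:
        slope = (h_asc[1] - h_asc[0]) / (fd_asc[1] - fd_asc[0])
        return float(h_asc[0] + slope * (target_fd - fd_asc[0]))
    if target_fd >= fd_asc[-1]:
        slope = (h_asc[-1] - h_asc[-2]) / (fd_asc[-1] - fd_asc[-2])
        return float(max(0.01, h_asc[-1] + slope * (target_fd - fd_asc[-1])))
    return float(np.interp(target_fd, fd_asc, h_asc))


def make_fractal_texture(
    spec: FractalTextureSpec, size: int = 256
) -> tuple[np.ndarray, float]:
    """Generate a binary planar texture and its ground-truth box dimension.

    * ``filled``: the full square, dimension 2.
    * ``sierpinski_carpet``: standard carpet at ``spec.depth``; requires
      ``size`` a power of 3; dimension log 8 / log 3 ~= 1.8928.
    * ``fbm``: the median-level contour of a fractional Brownian surface; the
      Hurst exponent is chosen through a calibrated response (anchored at the
      default 256 px size) so the expected measured box dimension equals
      ``target_fd``.
    """
    if size < 27:
        raise ValueError("size must be >= 27")
    if spec.pattern == "filled":
        return np.ones((size, size), dtype=bool), 2.0
    if spec.pattern == "sierpinski_carpet":
        return sierpinski_carpet(spec.depth, size), float(np.log(8) / np.log(3))
    hurst = _hurst_for_target_fd(spec.target_fd)
    surf = _fbm_surface(size, hurst, np.random.default_rng(spec.seed))
    above = surf > np.median(surf)
    # contour = boundary pixels of the excursion set (4-neighbour edges)
    contour = np.zeros_like(above)
    contour[:-1, :] |= above[:-1, :] != above[1:, :]
    contour[:, :-1] |= above[:, :-1] != above[:, 1:]
    return contour, float(spec.target_fd)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

STAGES = ("I", "II", "III")

#: Per-stage means/SDs of the three morphometric parameters and cuffing-sign
#: positivity rates used as generator defaults (stage I, II, III).
DEFAULT_FEATURE_MOMENTS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "wt_d": ((0.26, 0.30, 0.35), (0.02, 0.02, 0.03)),
    "avi_deg": ((8.27, 12.64, 16.92), (1.15, 1.87, 2.46)),
    "fd": ((1.41, 1.57, 1.68), (0.08, 0.09, 0.10)),
}
DEFAULT_CUFFING_RATES = (15 / 42, 11 / 16, 6 / 7)

#: Auxiliary clinical variables: per-stage (means, SDs), the morphometric
#: feature they correlate with, and the target Pearson correlation.
DEFAULT_AUXILIARIES: dict[str, dict] = {
    "calcification_score": {
        "means": (85.32, 93.47, 107.29),
        "sds": (10.32, 11.58, 14.87),
        "anchor": "avi_deg",
        "r": 0.612,
    },
    "lung_volume_l": {
        "means": (4.92, 4.63, 4.25),
        "sds": (0.51, 0.61, 0.58),
        "anchor": "fd",
        "r": -0.532,
    },
    "pa_diameter_mm": {
        "means": (21.37, 23.89, 26.54),
        "sds": (1.83, 1.97, 2.13),
        "anchor": "fd",
        "r": 0.479,
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic staged cohort.

    Within each stage the morphometric features are drawn from independent
    normals at the stated means/SDs; the cuffing sign is Bernoulli at the
    per-stage rate; auxiliaries are tied to their anchor feature through a
    Gaussian copula that hits the target within-stage correlation.
    """

    group_sizes: tuple[int, int, int] = (42, 16, 7)
    feature_moments: dict = field(default_factory=lambda: DEFAULT_FEATURE_MOMENTS)
    cuffing_rates: tuple[float, float, float] = DEFAULT_CUFFING_RATES
    auxiliaries: dict = field(default_factory=lambda: DEFAULT_AUXILIARIES)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        for name, (means, sds) in self.feature_moments.items():
            if any(s < 0 for s in sds):
                raise ValueError(f"negative SD for feature {name}")
        for name, aux in self.auxiliaries.items():
            if not -1.0 < aux["r"] < 1.0:
                raise ValueError(f"correlation target for {name} must be in (-1, 1)")
        if any(not 0.0 <= p <= 1.0 for p in self.cuffing_rates):
            raise ValueError("cuffing rates must be probabilities")


def correlated_normal(
    z_anchor: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Standard-normal draw with correlation ``r`` to ``z_anchor`` (Gaussian copula)."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must be in (-1, 1)")
    return r * z_anchor + np.sqrt(1.0 - r * r) * rng.standard_normal(len(z_anchor))


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Draw a per-patient table with columns stage, wt_d, avi_deg, fd, cuffing
    plus the configured auxiliary variables.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for gi, (stage, n) in enumerate(zip(STAGES, spec.group_sizes)):
        z = {name: rng.standard_normal(n) for name in spec.feature_moments}
        block = {"stage": np.repeat(stage, n)}
        for name, (means, sds) in spec.feature_moments.items():
            block[name] = means[gi] + sds[gi] * z[name]
        for name, aux in spec.auxiliaries.items():
            z_aux = correlated_normal(z[aux["anchor"]], aux["r"], rng)
            block[name] = aux["means"][gi] + aux["sds"][gi] * z_aux
        block["cuffing"] = (rng.random(n) < spec.cuffing_rates[gi]).astype(int)
        rows.append(pd.DataFrame(block))
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(len(df))])
    return df
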