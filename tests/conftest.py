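"""Shared fixtures: phantoms and cross-section stacks are built once per
session; every fixture's ground truth is known by construction."""

import numpy as np
import pytest

from bvbquant.bvb_metrics import AirwayMeasurement, MeasurementError, measure_wall
from bvbquant.core_volume import Centerline
from bvbquant.reformat import ObliquePlane, curved_planar_reformation, resample_plane
from bvbquant.synthetic_data import AirwayPhantomSpec, CuffSpec, make_airway_phantom


def axial_plane(extent=13.0, pixel_size=0.2, center=(0.0, 0.0, 0.0)):
    return ObliquePlane(
        center=np.asarray(center, dtype=float),
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 1.0, 0.0]),
        extent=(extent, extent),
        pixel_size=pixel_size,
    )


def straight_z_centerline(half_len=7.0, n=15):
    return Centerline(np.outer(np.linspace(-half_len, half_len, n), [0.0, 0.0, 1.0]))


def median_reference_walls(stack, n_rays=72):
    """Per-section stack-median wall (robust to cuff-contaminated sections)."""
    walls = []
    for sec in stack:
        try:
            walls.append(measure_wall(sec, n_rays=n_rays))
        except MeasurementError:
            walls.append(None)
    ok = [w for w in walls if w is not None]
    d = float(np.median([w.inner_diameter_d for w in ok]))
    wt = float(np.median([w.wall_thickness_wt for w in ok]))
    return [
        None
        if w is None
        else AirwayMeasurement(
            inner_diameter_d=d, wall_thickness_wt=wt, center_px=w.center_px
        )
        for w in walls
    ]


@pytest.fixture(scope="session")
def stage1_volume():
    """Noise-free stage-I design-point airway phantom (WT/D = 0.26)."""
    return make_airway_phantom(
        AirwayPhantomSpec(lumen_diameter_mm=4.0, wall_thickness_mm=1.04, noise_sd_hu=0.0)
    )


@pytest.fixture(scope="session")
def stage1_section(stage1_volume):
    return resample_plane(stage1_volume, axial_plane())


@pytest.fixture(scope="session")
def cuffed_stack():
    """CPR stack of a phantom wearing a full 3 mm cuff over 5 slices."""
    vol = make_airway_phantom(
        AirwayPhantomSpec(cuff=CuffSpec(thickness_mm=3.0, coverage_fraction=1.0, n_slices=5))
    )
    return curved_planar_reformation(
        vol, straight_z_centerline(), width=15.0, pixel_size=0.2, step=0.62
    )


@pytest.fixture(scope="session")
def cuffed_stack_walls(cuffed_stack):
    return median_reference_walls(cuffed_stack)
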