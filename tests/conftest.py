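"""Shared fixtures: small grids and the (expensive) phantom-study bundle."""

from __future__ import annotations

import numpy as np
import pytest

from tandemspect.grid import VolumeImage, VoxelGrid
from tandemspect.pipeline import RunConfig, run_phantom_study


@pytest.fixture(scope="session")
def clinical_spacing() -> tuple[float, float, float]:
    return (4.7952, 4.7952, 4.7952)


@pytest.fixture()
def small_grid(clinical_spacing) -> VoxelGrid:
    return VoxelGrid.centered((16, 16, 12), clinical_spacing)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def phantom_study_bundle():
    """Full HC + LC cylinder-phantom study at desk scale (shared: ~2 min).

    64x64x24 voxels at the clinical 4.7952 mm pitch (307 mm field of view
    around the 202 mm phantom), the clinical 32-view 3.5 min acquisition,
    60 all-view MLEM iterations, checkpoints every 10.
    """
    cfg = RunConfig(study="phantom", grid_shape=(64, 64, 24), seed=1)
    return run_phantom_study(cfg), cfg


@pytest.fixture(scope="session")
def sd_zero_patient_bundle():
    """Ideal-imaging, sd-zero synthetic tandem patient (criterion-free reuse)."""
    from tandemspect.pipeline import run_tandem_patient_study

    cfg = RunConfig(
        study="tandem_patient", grid_shape=(48, 48, 32), seed=7,
        n_patients=1, imaging_mode="ideal",
        patient=dict(
            n_lesions=2,
            kidney_suv_lu177=(2.1, 0.0), kidney_suv_ac225=(2.5, 0.0),
            lesion_suv_lu177=(2.1, 0.0), lesion_suv_ac225=(1.8, 0.0),
            kidney_ratio_sd=0.0, lesion_ratio_sd=0.0,
            kidney_half_life_h=(31.0, 0.0), lesion_half_life_h=(51.0, 0.0),
            lesion_volume_ml=(21.0, 0.0), p_increasing_uptake=0.0,
        ),
    )
    return run_tandem_patient_study(cfg), cfg


def uniform_cylinder_image(grid: VoxelGrid, radius_mm: float, height_mm: float,
                           conc: float) -> VolumeImage:
    x, y, z = grid.meshgrid()
    inside = (x**2 + y**2 <= radius_mm**2) & (np.abs(z) <= height_mm / 2)
    return VolumeImage(grid, np.where(inside, conc, 0.0),
                       "activity_conc_Bq_per_ml")
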