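"""Shared fixtures: calibrated banks at the problem sizes the tests use."""

import numpy as np
import pytest

import spatialvision as sv


@pytest.fixture(scope="session")
def tp():
    return sv.TransducerParams()


@pytest.fixture(scope="session")
def small_calib(tp):
    """A small foveal strip for fast filter-level checks."""
    grid = sv.VisualFieldGrid.horizontal_strip(
        max_ecc_deg=8.0, px_per_deg=32.0, height_deg=5.0, lead_deg=2.0)
    bank = sv.build_bank(grid)
    return sv.calibrate_bank(bank, tp)


@pytest.fixture(scope="session")
def csf_calib(tp):
    """Strip covering the CSF simulation grid (eccentricities to 24 deg)."""
    grid = sv.VisualFieldGrid.horizontal_strip(
        max_ecc_deg=24.0, px_per_deg=48.0, height_deg=10.0)
    bank = sv.build_bank(grid)
    return sv.calibrate_bank(bank, tp)


@pytest.fixture(scope="session")
def blur_calib(tp):
    """Wide strip for the blur experiments (eccentricities to 42 deg)."""
    grid = sv.VisualFieldGrid.horizontal_strip(
        max_ecc_deg=42.0, px_per_deg=32.0, height_deg=10.0)
    bank = sv.build_bank(grid)
    return sv.calibrate_bank(bank, tp)


@pytest.fixture(scope="session")
def scene_calib(tp):
    """The desk-scale 32-degree scene field at 512 px."""
    grid = sv.VisualFieldGrid.scene_scaled(512)
    bank = sv.build_bank(grid, zoning_step_octaves=0.25)
    return sv.calibrate_bank(bank, tp)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
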