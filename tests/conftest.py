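"""Shared fixtures: small phantom patients and cohorts, deterministic seeds."""

import numpy as np
import pytest

from prostaspec.cli import PipelineConfig
from prostaspec.io_formats import SequenceVolume
from prostaspec.registration import RegisteredCube
from prostaspec.synthetic_cohort import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> SyntheticCohortSpec:
    """A compact phantom spec for plumbing tests (fast, deterministic)."""
    return SyntheticCohortSpec(
        n_patients=8,
        grid_shape=(32, 32, 14),
        prostate_semi_axes=(22.0, 19.0, 16.0),
        volume_base_ml=0.6,
        volume_slope_ml=0.4,
        tumor_center_jitter_mm=2.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_volume(grid, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), label="ADC"):
    return SequenceVolume(
        grid=np.asarray(grid, dtype=float),
        spacing=spacing,
        origin=origin,
        sequence_label=label,
    )


def make_cube(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return RegisteredCube(voxels=np.asarray(voxels, dtype=float), spacing=spacing, origin=origin)


@pytest.fixture()
def identity_cube_factory():
    return make_cube
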