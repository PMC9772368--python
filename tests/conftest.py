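"""Shared fixtures: small synthetic lesions and cohorts sized for fast tests."""

import numpy as np
import pytest

from segdosim.masks import VoxelMask
from segdosim.synthetic import CohortConfig, generate_cohort, generate_true_lesion


def make_mask(occ, spacing=(1.0, 1.0, 1.0)):
    return VoxelMask(np.asarray(occ, dtype=bool), spacing)


def random_mask(rng, shape=(12, 12, 6), p=0.3, spacing=(1.0, 1.0, 1.0)):
    return VoxelMask(rng.random(shape) < p, spacing)


@pytest.fixture(scope="session")
def small_lesion():
    """A ~8 mL irregular lesion on a coarse grid; fast to re-voxelize."""
    return generate_true_lesion(
        8.0, 0.3, (2.0, 2.0, 2.5), seed=42, margin_mm=12.0, lesion_id="LFIX"
    )


def small_cohort_config(seed: int, n_lesions: int = 4) -> CohortConfig:
    """Reduced study conditions used for Monte-Carlo style tests."""
    return CohortConfig(
        n_lesions=n_lesions,
        volume_range_ml=(3.0, 30.0),
        grid_spacing_mm=(2.0, 2.0, 2.5),
        sigma_inter=2.0,
        sigma_intra=1.0,
        psf_sigma_mm=4.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config(seed=5))


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study design (20 lesions, 7 reads each).

    Session-scoped because generation takes tens of seconds; several
    acceptance checks share it.
    """
    return generate_cohort(CohortConfig(seed=20220715))
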