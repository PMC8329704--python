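"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from nfbpredict.synthgen import CohortConfig, PlantedEffect, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_cohort_config(**overrides) -> CohortConfig:
    """A desk-scale cohort: short runs, coarse grids, few ROIs."""
    base = dict(
        n_participants=8,
        n_sessions=2,
        runs_per_session=4,
        run_duration_s=12.0,
        fs_nfb=250.0,
        fs_eeg=250.0,
        eeg_duration_s=6.0,
        grid_shape=(10, 10, 10),
        n_volumes=60,
        tr_s=2.0,
        n_rois=6,
        effect_map=(
            PlantedEffect("eeg_power", {"roi": "left central"}, 0.8),
            PlantedEffect("alff", {"center": (5, 5, 5), "radius": 1.6}, 0.7),
            PlantedEffect("gmv", {"center": (4, 5, 5), "radius": 1.6}, 0.7),
            PlantedEffect("fc", {"edge": ("roi000", "roi003")}, 0.7),
        ),
        seed=7,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One fully generated multimodal cohort reused across tests."""
    cfg = small_cohort_config()
    dataset, gt = generate_cohort(cfg)
    return dataset, gt
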