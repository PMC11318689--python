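"""Shared fixtures: synthetic deployments and reference configurations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from phocoena import synthetic
from phocoena.synthetic import GenConfig, StateParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def well_separated_config(duration_h: float = 10.0, seed: int = 11, **overrides) -> GenConfig:
    """Three states sharing dive geometry but cleanly separated in the
    metrics the state model uses: activity levels far apart relative to the
    per-dive emission spread, a >=5x buzz-rate contrast, and buzzes placed
    through the water column (pelagic) versus at the bottom."""
    states = [
        StateParams(
            "nonfeeding", 60.0, 12.0, 8.0, 2.0, 30.0, 8.0, 0.0, 2.4, 1.9,
            bottom_fraction=0.12, buzz_placement="uniform", roll_sd_rad=0.10,
            activity_cv=0.2,
        ),
        StateParams(
            "pelagic", 60.0, 12.0, 8.0, 2.0, 30.0, 8.0, 3.0, 3.0, 2.4,
            bottom_fraction=0.12, buzz_placement="uniform", roll_sd_rad=0.20,
            activity_cv=0.2,
        ),
        StateParams(
            "bottom", 60.0, 12.0, 8.0, 2.0, 30.0, 8.0, 3.0, 2.7, 1.6,
            bottom_fraction=0.50, buzz_placement="bottom", roll_sd_rad=0.35,
            activity_cv=0.2,
        ),
    ]
    tpm = [
        [0.85, 0.10, 0.05],
        [0.10, 0.80, 0.10],
        [0.10, 0.15, 0.75],
    ]
    cfg = GenConfig(
        states=states,
        context_tpms=[tpm],
        context_weights=[1.0],
        night_buzz_multiplier=1.0,
        night_pelagic_multiplier=1.0,
        duration_h=duration_h,
        seed=seed,
    )
    import dataclasses

    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_deployment():
    """Three hours of realistic-regime data with ground truth."""
    cfg = synthetic.default_config(duration_h=3.0, seed=1)
    record, truth = synthetic.generate_deployment(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def separated_deployment():
    """Ten hours of well-separated-state data with ground truth."""
    cfg = well_separated_config(duration_h=10.0, seed=11)
    record, truth = synthetic.generate_deployment(cfg)
    return cfg, record, truth


@pytest.fixture(scope="session")
def small_kinematics(small_deployment):
    from phocoena import sensor

    _, record, _ = small_deployment
    return sensor.prepare_kinematics(record, cut=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
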