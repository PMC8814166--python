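"""Shared fixtures.

The expensive session fixtures (full-architecture network trainings, the
default 24-subject cohort) are built once and shared between the unit tests
and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ennflow import ann, synth

MASTER_SEED = 1234


@pytest.fixture(scope="session")
def brain() -> synth.GroundTruthBrain:
    """Default-configuration ground-truth brain."""
    return synth.build_ground_truth(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def cohort8(brain) -> synth.SyntheticCohort:
    """Small cohort for FC and selection tests."""
    return synth.generate_cohort(8, brain, seed=MASTER_SEED + 1)


@pytest.fixture(scope="session")
def cohort24(brain) -> synth.SyntheticCohort:
    """Default 24-subject cohort for the evaluation suite."""
    return synth.generate_cohort(24, brain, seed=MASTER_SEED + 2)


@pytest.fixture(scope="session")
def trained_ann():
    """Full-architecture reference network trained to the stop rule."""
    params, trace = ann.train_ann(ann.AnnConfig(seed=MASTER_SEED))
    return params, trace


@pytest.fixture(scope="session")
def trained_ann_alt():
    """Second training with a different seed (replicability checks)."""
    params, trace = ann.train_ann(ann.AnnConfig(seed=MASTER_SEED + 99))
    return params, trace


@pytest.fixture(scope="session")
def trained_rsm(trained_ann) -> np.ndarray:
    params, _ = trained_ann
    return ann.probe_hidden_rsm(params)


@pytest.fixture(scope="session")
def small_ann():
    """Cheap small network for forward/backward mechanics tests."""
    cfg = ann.AnnConfig(n_hidden=32, seed=0)
    rng = np.random.default_rng(0)
    return cfg, ann.init_parameters(cfg, rng)
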