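import logging

import numpy as np
import pytest

from fstgc import CohortConfig, EffectSpec, NuisanceSpec, simulate_cohort

logging.getLogger("fstgc").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


@pytest.fixture(scope="session")
def quiet_nuisance():
    """Nuisance-free simulation spec for clean estimator checks."""
    return NuisanceSpec(drift_amplitude=0.0, n_motion=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny deterministic cohort reused by interface/pipeline tests."""
    config = CohortConfig(
        n_subjects=8,
        n_timepoints=60,
        seed=42,
        effect_map=[EffectSpec("L.dLPFC", "R.dLPFC", "snp1", 0.2)],
        behavior_couplings=[],
    )
    return simulate_cohort(config)
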