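import numpy as np
import pytest

import vfdecomp as vd


@pytest.fixture(scope="session")
def grid():
    return vd.canonical_grid()


@pytest.fixture(scope="session")
def bank():
    return vd.canonical_bank()


@pytest.fixture(scope="session")
def bank_atset(bank):
    """The generator's pattern bank wrapped as a fitted archetype set.

    Used wherever a decomposition needs archetypes but the test is not about
    the fitting itself (the true patterns are trivially in their own hull).
    """
    return vd.ArchetypeSet(
        k=bank.k,
        patterns=bank.patterns.copy(),
        hull_coefficients=np.eye(bank.k),
        fit_rss=0.0,
        seed=None,
        n_iter=0,
        converged=True,
        labels=bank.labels,
    )


@pytest.fixture(scope="session")
def small_longitudinal(bank):
    """Small two-eye-per-patient longitudinal cohort with ground truth."""
    cfg = vd.SimulationConfig(n_patients=25, visits_per_eye=7, seed=11)
    return vd.simulate_longitudinal(bank, cfg)


@pytest.fixture(scope="session")
def cross_section(bank):
    cfg = vd.SimulationConfig(noise_sd_db=1.0, seed=5)
    tests, truth = vd.simulate_cross_section(bank, 300, cfg)
    return tests, truth
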