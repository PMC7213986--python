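"""Shared synthetic cohorts (session-scoped: simulation is the slow part)."""

import numpy as np
import pytest

import ktrcycle as k


@pytest.fixture(scope="session")
def release_cohort():
    """Default quiescence-release cohort, 300 cells."""
    return k.simulate_quiescence_release(k.GeneratorParams(n_cells=300, seed=101))


@pytest.fixture(scope="session")
def release_records(release_cohort):
    return k.detect_events(release_cohort)


@pytest.fixture(scope="session")
def noisefree_release():
    """All-activating, noise-free release cohort (exact-recovery oracle)."""
    params = k.GeneratorParams(n_cells=100, noise_sd=0.0, p_activate=1.0, seed=77)
    return k.simulate_quiescence_release(params)


@pytest.fixture(scope="session")
def cycling_cohort():
    """Mitotic-exit cohort with >= 10 h of post-anaphase recording."""
    params = k.GeneratorParams(n_cells=400, duration=14.0, seed=202)
    return k.simulate_cycling(params)


@pytest.fixture(scope="session")
def cycling_records(cycling_cohort):
    return k.detect_events(cycling_cohort)


@pytest.fixture(scope="session")
def sg2_cohort():
    """S/G2 cells acutely CDK4/6-inhibited (correction-factor estimation)."""
    return k.simulate_sg2_inhibited(120, noise_sd=0.02, seed=303)


@pytest.fixture(scope="session")
def stress_cohort():
    """Stress at 11 h on a released cohort (default logistic dose-response)."""
    base = k.simulate_quiescence_release(k.GeneratorParams(n_cells=1500, seed=404))
    return k.apply_perturbation(base, k.PerturbationSpec(kind="stress", t_add=11.0))


@pytest.fixture(scope="session")
def stress_records(stress_cohort):
    return k.detect_events(stress_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
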