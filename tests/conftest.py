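import numpy as np
import pytest

from neuroexhaust import synth


@pytest.fixture(scope="session")
def cc_protocol():
    return synth.default_cc_protocol()


@pytest.fixture(scope="session")
def control_cc(cc_protocol):
    """One control multi-spiking cell under the standard step protocol."""
    return synth.simulate_current_clamp(
        synth.ARCHETYPES["T3-control"], cc_protocol, seed=2,
        cell_id="ctl", genotype="control")


@pytest.fixture(scope="session")
def patient_cc(cc_protocol):
    return synth.simulate_current_clamp(
        synth.ARCHETYPES["T3-patient"], cc_protocol, seed=2,
        cell_id="pat", genotype="patient")


@pytest.fixture(scope="session")
def small_cohort():
    """12-cell jittered cohort, 4 of each firing class (T3 = control)."""
    plan = synth.standard_cohort_plan(
        {"T1": 4, "T2": 4, "T3-control": 4}, seed=5)
    recs, truth = synth.generate_cohort(plan)
    return recs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
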