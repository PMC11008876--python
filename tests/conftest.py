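import pytest

from causalpress.pipeline import prepare_trials, preset_params
from causalpress.simulate import simulate_cohort


@pytest.fixture(scope="session")
def oracles():
    from causalpress.networks import Structure, normative_table, table_spec

    return {s.value: normative_table(table_spec(s)) for s in Structure}


@pytest.fixture(scope="session")
def paperlike_prepared():
    """Small paper-like cohort, fully annotated and coded (exp2: has confidence)."""
    trials = simulate_cohort(6, master_seed=11, experiment="exp2")
    prepared, report = prepare_trials(trials, experiment="exp2")
    return prepared, report


@pytest.fixture(scope="session")
def normative_trials():
    """Noise-free normative responders (2 participants)."""
    params, _ = preset_params("normative")
    return simulate_cohort(2, params=params, master_seed=5)
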