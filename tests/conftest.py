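import dataclasses

import pytest

from pulsechase import conveyor, enrichment, synthesis


@pytest.fixture(scope="session")
def grid():
    return conveyor.SimulationGrid(dt=0.1, horizon=60.0)


@pytest.fixture(scope="session")
def avail():
    return conveyor.LabelAvailability(amplitude=0.05)


@pytest.fixture(scope="session")
def standards():
    return {
        enrichment.DNA_CHANNEL: synthesis.identity_standards(enrichment.DNA_CHANNEL),
        enrichment.GLUCOSE_CHANNEL: synthesis.identity_standards(
            enrichment.GLUCOSE_CHANNEL
        ),
    }


@pytest.fixture(scope="session")
def noise_free_scenario():
    return dataclasses.replace(
        synthesis.TreatmentScenario(),
        count_noise_cv=0.0,
        ms_area_noise_cv=0.0,
        between_subject_cv=0.0,
    )


@pytest.fixture(scope="session")
def small_noise_free_trial(standards, noise_free_scenario):
    """Three subjects per arm, no noise: measurements equal truth exactly."""
    design = synthesis.default_design(seed=11, n_per_arm=3)
    table = synthesis.generate_trial(
        design, None, noise_free_scenario, master_seed=11
    )
    return design, table
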