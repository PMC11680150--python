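import pytest

from feedenergy import datasets
from feedenergy.synthetic import NoiseModel, simulate_trial, youden_design


@pytest.fixture(scope="session")
def panel():
    return datasets.cereal_panel()


@pytest.fixture(scope="session")
def diets():
    return datasets.trial_diets()


@pytest.fixture(scope="session")
def true_params():
    return datasets.default_true_params()


@pytest.fixture(scope="session")
def design13x6(diets):
    return youden_design(13, 6, diets=sorted(diets))


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseModel(
        fecal_energy_cv=0.0,
        urinary_energy_cv=0.0,
        intake_cv=0.0,
        nutrient_conc_cv=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def zero_noise_records(true_params, diets, design13x6, zero_noise):
    return simulate_trial(true_params, diets.values(), design13x6, noise=zero_noise)
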