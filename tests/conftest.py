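import numpy as np
import pytest

from grplate import (
    DrugSpec,
    EdgeField,
    NoiseModel,
    SimulationConfig,
    TrueDoseResponse,
    generate_dataset,
    gr_table,
)

NO_NOISE = NoiseModel(cv_well=0.0, sigma_plate=0.0, sigma_day=0.0, sigma_day_potency=0.0)


@pytest.fixture(scope="session")
def two_drug_truth():
    return (
        DrugSpec("alpha", TrueDoseResponse(gr_inf=-0.5, gec50=0.1, hill=2.0)),
        DrugSpec("beta", TrueDoseResponse(gr_inf=0.2, gec50=0.05, hill=1.5), atp_bias=2.0),
    )


@pytest.fixture(scope="session")
def noiseless_config(two_drug_truth):
    """Small deterministic study with no noise and no edge field."""
    return SimulationConfig(
        drugs=two_drug_truth,
        doses_per_drug=8,
        top_dose=10.0,
        n_bio=2,
        n_plates=2,
        n_wells=2,
        n_controls=24,
        n_t0_wells=48,
        noise=NO_NOISE,
        edge=EdgeField(edge_frac=0.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate_dataset(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_gr(noiseless_dataset):
    return gr_table(noiseless_dataset)


@pytest.fixture(scope="session")
def noisy_config(two_drug_truth):
    """Same structure with the default-scale noise hierarchy."""
    return SimulationConfig(
        drugs=two_drug_truth,
        doses_per_drug=8,
        top_dose=10.0,
        n_bio=3,
        n_plates=3,
        n_wells=3,
        n_controls=24,
        n_t0_wells=96,
        noise=NoiseModel(cv_well=0.05, sigma_plate=0.02, sigma_day=0.05,
                         sigma_day_potency=0.10),
        edge=EdgeField(edge_frac=0.0),
        seed=7,
    )


def brute_force_se(values):
    """Independent oracle for the SE formulas: explicit loops, no numpy."""
    values = [float(v) for v in values]
    n = len(values)
    mu = sum(values) / n
    sigma = (sum((x - mu) ** 2 for x in values) / (n - 1)) ** 0.5
    return sigma / n**0.5
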