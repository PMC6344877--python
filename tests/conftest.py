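import numpy as np
import pytest

from regulonkit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(
        seed=11,
        n_constant=3, n_direct=3, n_cooperative=3,
        n_promoters_dependent=10, n_promoters_independent=10,
        n_operons=3, operon_size=3,
        genome_length=40000,
        n_insignificant_peaks=2,
        frac_unassignable=0.2,
    )


@pytest.fixture(scope="session")
def regulators(small_config):
    return sd.make_regulator_profiles(small_config)


@pytest.fixture(scope="session")
def fixtures(small_config):
    return sd.make_genomic_fixtures(small_config)


@pytest.fixture(scope="session")
def expression_bundle(small_config, regulators):
    params = sd.default_param_sets(small_config, regulators)
    matrix, truth = sd.simulate_targets(small_config, params, regulators)
    return matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
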