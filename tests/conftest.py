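import pytest

from tetswitch import ExperimentDesign, generate_experiment, table1_params


@pytest.fixture(scope="session")
def p():
    """The packaged best-fit parameter set."""
    return table1_params()


@pytest.fixture(scope="session")
def noiseless_dataset(p):
    """The default 24-course campaign without replicate noise."""
    design = ExperimentDesign(noise_cv=0.0, noise_floor_frac=0.0)
    return generate_experiment(p, design, seed=0)
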