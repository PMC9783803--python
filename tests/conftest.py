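import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def qtaim_table(tmp_path_factory):
    from hbridge.fixtures import generate_fixture

    outdir = tmp_path_factory.mktemp("tables")
    [path] = generate_fixture("table2_csv", outdir=outdir)
    return path


@pytest.fixture(scope="session")
def sapt_table(tmp_path_factory):
    from hbridge.fixtures import generate_fixture

    outdir = tmp_path_factory.mktemp("tables_sapt")
    [path] = generate_fixture("table3_csv", outdir=outdir)
    return path


@pytest.fixture(scope="session")
def harmonic_model():
    from hbridge.model_systems import ModelPotential

    return ModelPotential(kind="harmonic")


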