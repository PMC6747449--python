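import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def varicus_record():
    from mitocmp import datasets

    return datasets.thaparocleidus_varicus()


@pytest.fixture(scope="session")
def asoti_record():
    from mitocmp import datasets

    return datasets.thaparocleidus_asoti()


@pytest.fixture(scope="session")
def synthetic_pair():
    """Two generated thaparocleidus-preset genomes with their ground truth."""
    from mitocmp import synthetic_data as syn

    a = syn.generate(syn.preset_spec("thaparocleidus", 1))
    b = syn.generate(syn.preset_spec("thaparocleidus", 2))
    return a, b
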