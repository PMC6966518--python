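import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1_records():
    """The published myosin TAILS peptides, parsed by the package reader."""
    from gelascan import datasets, degradome

    return degradome.parse_peptide_table(datasets.MYOSIN_TAILS_TSV)
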