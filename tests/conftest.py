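import pytest

from landingpad.synth_fixtures import (
    FixtureParams,
    example_cassette,
    generate_fixture,
    synthetic_codon_table,
)


@pytest.fixture(scope="session")
def fixture():
    """The standard study-condition fixture: 2 chromosomes, 5 recoverable
    planted loci, one decoy of each class per chromosome."""
    return generate_fixture(FixtureParams(seed=1))


@pytest.fixture(scope="session")
def fixture_dir(fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    paths = fixture.write(outdir)
    return paths


@pytest.fixture(scope="session")
def codon_table():
    return synthetic_codon_table(seed=1)


@pytest.fixture(scope="session")
def cassette_parts(codon_table):
    return example_cassette(codon_table, seed=1)
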