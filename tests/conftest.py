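import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    from palmpattern import fixtures

    return fixtures.load_catalog()


@pytest.fixture(scope="session")
def palmi(catalog):
    return catalog["Allopodocotyle palmi"]


@pytest.fixture(scope="session")
def maternus(catalog):
    return catalog["Prosorhynchus maternus"]


@pytest.fixture(scope="session")
def grouper_key():
    from palmpattern import keys

    return keys.load_key(keys.packaged_key_path())


@pytest.fixture(scope="session")
def keyed_taxa(catalog):
    """The seven profiles the packaged key covers."""
    return {
        name: p
        for name, p in catalog.items()
        if name.startswith("Allopodocotyle") and "Rueckert" not in name
    }


@pytest.fixture(scope="session")
def palmi_specimens():
    """22 seeded synthetic gravid worms from the A. palmi profile."""
    from palmpattern import fixtures

    return fixtures.synth_specimens(
        fixtures.SynthSpec(taxon="Allopodocotyle palmi", n=22, seed=11)
    )
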