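import pytest

from nanomcr import build_campaign, builtin_registry, default_campaign_bank, generate_bank


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def study_bank():
    """Bank at the reference campaign class sizes (316 blocks + 20 reagents)."""
    return default_campaign_bank(seed=1)


@pytest.fixture(scope="session")
def study_campaign(registry, study_bank):
    """The full 16-scheme x 96-well sparse-matrix design."""
    return build_campaign(list(registry), study_bank, n_per_scheme=96, seed=1)


@pytest.fixture(scope="session")
def tiny_bank():
    """A small bank covering every variable class, for fast exact checks."""
    return generate_bank(
        {
            "amidine": 3,
            "aldehyde": 4,
            "ketone": 3,
            "isocyanide": 5,
            "carboxylic_acid": 4,
            "primary_amine": 4,
            "secondary_amine": 3,
            "special": 5,
        },
        seed=7,
    )
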