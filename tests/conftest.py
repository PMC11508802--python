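import pytest
from hypothesis import HealthCheck, settings

from pollensift.simdata import (
    DEFAULT_FWD_PRIMER,
    DEFAULT_REV_PRIMER,
    make_reference_set,
)
from pollensift.taxonomy import TaxonLineage

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_lineages():
    """Three plant lineages: two congeneric species plus an outgroup."""
    return {
        "faba": TaxonLineage(
            ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Fabales",
             "Fabaceae", "Vicia", "Vicia faba")
        ),
        "sativa": TaxonLineage(
            ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Fabales",
             "Fabaceae", "Vicia", "Vicia sativa")
        ),
        "urtica": TaxonLineage(
            ("Viridiplantae", "Streptophyta", "Magnoliopsida", "Rosales",
             "Urticaceae", "Urtica", "Urtica dioica")
        ),
    }


@pytest.fixture(scope="session")
def small_db():
    """Four mutually divergent synthetic amplicons with named genera."""
    return make_reference_set(
        4, amplicon_len=550, seed=11,
        genus_names=["Vicia", "Tulipa", "Urtica", "Pinus"],
    )


@pytest.fixture(scope="session")
def primers():
    return DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER
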