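import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from betadiv import IncidenceMatrix, SyntheticConfig, generate_metacommunity

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def build_incidence(rows):
    """IncidenceMatrix from {(estuary, site, replicate): iterable-of-taxa}."""
    taxa = sorted({t for taxa in rows.values() for t in taxa})
    if not taxa:
        taxa = ["placeholder"]
    data = pd.DataFrame(
        [[1 if t in present else 0 for t in taxa] for present in rows.values()],
        index=pd.MultiIndex.from_tuples(rows.keys(), names=("estuary", "site", "replicate")),
        columns=taxa,
    )
    return IncidenceMatrix(data)


@pytest.fixture
def toy_site():
    """One site with replicates {A,B}, {A}, {A} — the worked rarefaction toy."""
    return build_incidence(
        {
            ("E1", "S1", "R1"): {"A", "B"},
            ("E1", "S1", "R2"): {"A"},
            ("E1", "S1", "R3"): {"A"},
        }
    )


@pytest.fixture
def toy_estuary():
    """Two sites pooling {A,B} and {A,C,D}: gamma-estuary 4, beta-conn 2 and 1."""
    return build_incidence(
        {
            ("E1", "S1", "R1"): {"A"},
            ("E1", "S1", "R2"): {"B"},
            ("E1", "S2", "R1"): {"A", "C"},
            ("E1", "S2", "R2"): {"C", "D"},
        }
    )


@pytest.fixture(scope="session")
def small_meta():
    cfg = SyntheticConfig(
        n_estuaries=3, n_sites=5, n_replicates=6, pool_size=40, seed=2026
    )
    return generate_metacommunity(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
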