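import numpy as np
import pytest

from nrbpkit.fixtures import kinase_seed, toy_filter_tables
from nrbpkit.synthetic import FamilySimConfig, simulate_family
from nrbpkit.triad import build_profile


@pytest.fixture(scope="session")
def toy_filter():
    """Packaged 10-candidate filter fixture: (forward, reverse, expected, config, lengths)."""
    return toy_filter_tables()


@pytest.fixture(scope="session")
def seed_profile():
    """Profile built from the packaged synthetic kinase-domain seed."""
    records, spec = kinase_seed()
    return build_profile(records, spec)


@pytest.fixture(scope="session")
def mixed_family():
    """Small simulated family with intact P1/invertebrate and degenerate P2."""
    config = FamilySimConfig(
        n_leaves_per_clade=10,
        seq_length=120,
        base_rate=0.05,
        rate_multiplier_fast_clade=2.0,
        seed=7,
        triad_state_per_clade={
            "invertebrate": "intact", "P1": "intact", "P2": "degenerate"
        },
    )
    return simulate_family(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
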