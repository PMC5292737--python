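import random

import pytest

from r2ht import io
from r2ht.hosts import load_fixture_host_tree

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA", "ATG")
]


def make_clean_orf(n_nt: int, rng: random.Random, stop: str = "TAG") -> str:
    """ATG + sense codons + stop, total length n_nt (multiple of 3)."""
    assert n_nt % 3 == 0 and n_nt >= 9
    k = n_nt // 3 - 2
    return "ATG" + "".join(rng.choice(SENSE_CODONS) for _ in range(k)) \
        + stop


@pytest.fixture(scope="session")
def host():
    return load_fixture_host_tree()


@pytest.fixture(scope="session")
def distmats():
    return io.load_published_distances()


@pytest.fixture(scope="session")
def mapping():
    return io.load_fixture_mapping()


@pytest.fixture(scope="session")
def indel_profiles():
    return io.load_fixture_indel_profiles()


SIX_HT_PAIRS = {
    frozenset(p) for p in [
        ("R2Bgb", "R2Brfun"), ("R2Bgb", "R2Brdel"),
        ("R2Bgm", "R2Brfun"), ("R2Bgm", "R2Brdel"),
        ("R2Bgmdel", "R2Brfun"), ("R2Bgmdel", "R2Brdel"),
    ]
}


@pytest.fixture(scope="session")
def six_ht_pairs():
    return set(SIX_HT_PAIRS)
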