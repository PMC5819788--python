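import pytest

from karyokit.synth import SPECIES_ORDER, fixtures

#: Published per-species expectations the fixtures must reproduce:
#: (2n, ploidy, x, genome formula, (45S signals, bearing), (5S signals, bearing), TML um)
SPECIES_EXPECTED = {
    "P. brachystachys": (12, 2, 6, "A", (2, 2), (4, 2), 50.2),
    "P. canariensis": (12, 2, 6, "A", (2, 2), (4, 2), 35.0),
    "P. aquatica": (28, 4, 7, "B/C", (4, 4), (12, 7), 49.6),
    "P. minor": (28, 4, 7, "B/C", (2, 2), (16, 14), 38.9),
    "P. paradoxa": (14, 2, 7, "B", (2, 2), (2, 2), 30.3),
    "P. caroliniana": (28, 4, 7, "BB", (4, 4), (4, 4), 47.6),
    "P. coerulescens": (14, 2, 7, "B", (2, 2), (3, 3), 49.6),
    "P. arundinacea": (28, 4, 7, "BB", (4, 4), (2, 2), 46.0),
}

POLYPLOIDY_EXPECTED = {
    "P. brachystachys": "DIPLOID",
    "P. canariensis": "DIPLOID",
    "P. aquatica": "ALLOPOLYPLOID",
    "P. minor": "ALLOPOLYPLOID",
    "P. paradoxa": "DIPLOID",
    "P. caroliniana": "AUTOPOLYPLOID",
    "P. coerulescens": "DIPLOID",
    "P. arundinacea": "AUTOPOLYPLOID",
}


@pytest.fixture(scope="session")
def fx():
    return fixtures()


@pytest.fixture(scope="session")
def species_names():
    return list(SPECIES_ORDER)
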