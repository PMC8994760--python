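import numpy as np
import pytest

from herbaudit import datasets
from herbaudit.prescription import PHMEntry, Prescription, TaxonName


@pytest.fixture(scope="session")
def ygw():
    return datasets.load_bundled_prescription("YGW")


@pytest.fixture(scope="session")
def njw():
    return datasets.load_bundled_prescription("NJW")


@pytest.fixture(scope="session")
def dhw():
    return datasets.load_bundled_prescription("DHW")


@pytest.fixture(scope="session")
def byw():
    return datasets.load_bundled_prescription("BYW")


@pytest.fixture
def toy_rx():
    """Two materials, three species, one shared genus (Alpha)."""
    return Prescription(
        preparation="TOY",
        phms=(
            PHMEntry("material one",
                     frozenset({TaxonName.parse("Alpha one"),
                                TaxonName.parse("Alpha two")})),
            PHMEntry("material two",
                     frozenset({TaxonName.parse("Beta one")}), processed=True),
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
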