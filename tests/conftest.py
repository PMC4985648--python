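import numpy as np
import pytest

from orloss.pseudogenes import ReferenceProfile
from orloss.sequences import SENSE_CODONS
from orloss.simulate import default_tm_intervals, waterbird_species_tree


def make_cds(rng: np.random.Generator, n_codons: int = 310) -> str:
    """Random intact CDS: ATG + sense codons + TAA."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def reference(rng):
    """A 310-codon reference OR with synthetic 7-TM intervals."""
    return ReferenceProfile(
        locus="ORX",
        cds=make_cds(rng, 310),
        tm_intervals=default_tm_intervals(310),
    )


@pytest.fixture
def waterbird_tree():
    return waterbird_species_tree()
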