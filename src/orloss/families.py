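"""OR gene family and class assignment by best hit against an exemplar panel.

Olfactory receptor families 51-56 form Class I (receptors thought to
bind water-borne ligands) and families 1-14 Class II (air-borne
ligands).  Queries are assigned to the family of their highest-scoring
global protein alignment against a user-supplied panel of exemplar
sequences.  This is a best-hit stand-in for profile-HMM family scanning
and is not expected to reproduce HMM-based assignments exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from . import _align

CLASS_I_FAMILIES = frozenset(range(51, 57))
CLASS_II_FAMILIES = frozenset(range(1, 15))

_FAMILY_TAG = re.compile(r"family[:=](\d+)")


def family_class(family: int) -> str:
    """Class of an OR family id: 51-56 -> 'I', 1-14 -> 'II'."""
    if family in CLASS_I_FAMILIES:
        return "I"
    if family in CLASS_II_FAMILIES:
        return "II"
    raise ValueError(f"family {family} is outside the classified ranges 1-14 and 51-56")


@dataclass(frozen=True)
class FamilyExemplar:
    family: int
    protein: str
    name: str = ""

    def __post_init__(self) -> None:
        family_class(self.family)  # validates the id
        if not self.protein:
            raise ValueError("empty exemplar protein")

    @property
    def or_class(self) -> str:
        return family_class(self.family)


@dataclass(frozen=True)
class FamilyAssignment:
    family: int
    or_class: str
    score: float
    exemplar: str


def parse_family_tag(description: str) -> int:
    """Extract the family id from a ``family:<n>`` FASTA header tag."""
    m = _FAMILY_TAG.search(description)
    if not m:
        raise ValueError(f"no family:<n> tag in header {description!r}")
    return int(m.group(1))


def assign_family(
    query_protein: str, panel: list[FamilyExemplar]
) -> FamilyAssignment:
    """Best-hit family assignment for a query protein.

    Ties on alignment score are broken by the lowest family id (then by
    exemplar name, for stability within a family).
    """
    if not query_protein:
        raise ValueError("empty query protein")
    if not panel:
        raise ValueError("empty exemplar panel")
    aligner = _align.protein_aligner()
    best: tuple[float, int, str] | None = None
    for ex in panel:
        score = aligner.score(ex.protein, query_protein)
        key = (-score, ex.family, ex.name)
        if best is None or key < best:
            best = key
    score, family, name = -best[0], best[1], best[2]
    return FamilyAssignment(
        family=family, or_class=family_class(family), score=score, exemplar=name
    )
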