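"""Contingency table construction and the exact Fisher test.

The central comparison is a 2x2 table of pseudogenized vs intact OR
sequence observations in two lineage groups (e.g. penguins vs non-penguin
waterbirds).  The counting unit is a (species, locus) sequence
observation, not a distinct locus, matching how repertoire surveys tally
their totals; loci absent from a genome are excluded.

The two-sided exact p-value sums, over all tables with the observed
margins, the hypergeometric probabilities that do not exceed the
probability of the observed table (the standard minimum-likelihood rule).
Computation is in log space via ``lgamma`` for numerical safety.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass
from math import exp, lgamma
from numbers import Integral

logger = logging.getLogger(__name__)

INTACT = "intact"
PSEUDOGENE = "pseudogene"
ABSENT = "absent"

#: relative slack when comparing table probabilities for two-sided inclusion
#: (log-space absolute tolerance; same convention as R's fisher.test)
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are lineage groups, columns (pseudogene, intact).

    ``a``/``b`` are group-1 pseudogene/intact counts, ``c``/``d`` group 2.
    """

    a: int
    b: int
    c: int
    d: int
    group1: str = "group1"
    group2: str = "group2"

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, Integral) or v < 0:
                raise ValueError("contingency counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def proportions(self) -> tuple[float, float]:
        """Pseudogene fraction per group (nan-free: empty row gives 0.0)."""
        r1 = self.a + self.b
        r2 = self.c + self.d
        return (self.a / r1 if r1 else 0.0, self.c / r2 if r2 else 0.0)


def contingency_table(
    classifications: Mapping[tuple[str, str], str],
    groups: Mapping[str, str],
    group_order: tuple[str, str] | None = None,
) -> ContingencyTable:
    """Tally (species, locus) statuses into a 2x2 group table.

    Parameters
    ----------
    classifications :
        ``(species, locus) -> status`` with status in ``{"intact",
        "pseudogene", "absent", ...}``.  Statuses other than intact /
        pseudogene are excluded (their count is logged).
    groups :
        ``species -> group label``; exactly two labels must occur.
    group_order :
        Which label is row 1 and which row 2.  Defaults to sorted order.
    """
    if not classifications:
        raise ValueError("no classifications supplied")
    labels = set(groups.values())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two group labels, got {sorted(labels)}")
    if group_order is None:
        group_order = tuple(sorted(labels))  # type: ignore[assignment]
    elif set(group_order) != labels:
        raise ValueError("group_order does not match the labels in `groups`")

    counts = {g: {INTACT: 0, PSEUDOGENE: 0} for g in group_order}
    excluded = 0
    for (species, _locus), status in classifications.items():
        if species not in groups:
            raise ValueError(f"species {species!r} has no group assignment")
        if status not in (INTACT, PSEUDOGENE):
            excluded += 1
            continue
        counts[groups[species]][status] += 1
    if excluded:
        logger.info("excluded %d observations with status outside {intact, pseudogene}", excluded)

    g1, g2 = group_order
    return ContingencyTable(
        a=counts[g1][PSEUDOGENE],
        b=counts[g1][INTACT],
        c=counts[g2][PSEUDOGENE],
        d=counts[g2][INTACT],
        group1=g1,
        group2=g2,
    )


def _log_hypergeom_pmf(x: int, r1: int, c1: int, n: int) -> float:
    """log P(X = x) for the 2x2 table with row-1 margin r1, col-1 margin c1, total n."""

    def lchoose(n_: int, k_: int) -> float:
        return lgamma(n_ + 1) - lgamma(k_ + 1) - lgamma(n_ - k_ + 1)

    return lchoose(r1, x) + lchoose(n - r1, c1 - x) - lchoose(n, c1)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided exact Fisher p-value for a 2x2 table.

    Enumerates the hypergeometric support at fixed margins and sums the
    probabilities of all tables no more likely than the observed one
    (within relative tolerance 1e-7, to absorb floating-point ties).

    A degenerate table (an all-zero row or column) carries no information
    about association; by convention p = 1.0 is returned with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = table.total
    if min(r1, r2, c1, c2) == 0:
        logger.warning("degenerate margin in contingency table %s; p = 1.0", (a, b, c, d))
        return 1.0

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    lp_obs = _log_hypergeom_pmf(a, r1, c1, n)
    cutoff = lp_obs + _REL_TOL
    p = sum(
        exp(lp)
        for x in range(lo, hi + 1)
        if (lp := _log_hypergeom_pmf(x, r1, c1, n)) <= cutoff
    )
    # when every outcome is included the total is exactly 1 by construction;
    # absorb float summation error
    if p > 1.0 - 1e-12:
        return 1.0
    return p
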