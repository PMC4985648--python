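"""Codon-aware disruption calling against an intact reference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orloss import ORSequence, call_disruptions, classify_terminal_position
from orloss.pseudogenes import DELETION, INSERTION, NONSENSE, ReferenceProfile
from orloss.sequences import SENSE_CODONS, STOP_CODONS, translate

from conftest import make_cds


def as_query(seq: str, qid: str = "q") -> ORSequence:
    return ORSequence(id=qid, species="sp", seq=seq, source="synthetic")


# -- independent placement oracle --------------------------------------------


def oracle_deletion_position(ref: str, start: int, length: int) -> int:
    """Leftmost start producing the same deleted sequence (exhaustive)."""
    target = ref[:start] + ref[start + length :]
    for s in range(0, start + 1):
        if ref[:s] + ref[s + length :] == target:
            return s
    raise AssertionError("unreachable")


def oracle_insertion_position(ref: str, mutant: str, length: int) -> int:
    """Leftmost position p with mutant == ref[:p] + seg + ref[p:] (exhaustive)."""
    for p in range(0, len(ref) + 1):
        if mutant == ref[:p] + mutant[p : p + length] + ref[p:]:
            return p
    raise AssertionError("unreachable")


# -- worked examples ----------------------------------------------------------


def test_identical_query_is_intact(reference):
    rep = call_disruptions(as_query(reference.cds), reference)
    assert rep.status == "intact"
    assert rep.disruptions == ()
    assert rep.first_disruption_fraction is None
    assert rep.identity == 1.0
    assert classify_terminal_position(rep) == "none"


def test_two_bp_deletion_called_with_induced_stops(reference):
    """A 2-bp deletion at codon 10 shifts the frame; the deletion and any
    downstream frame-induced stops are reported, status pseudogene."""
    nt0 = 3 * 9
    mutant = reference.cds[:nt0] + reference.cds[nt0 + 2 :]
    rep = call_disruptions(as_query(mutant), reference)
    assert rep.is_pseudogene
    dels = [d for d in rep.disruptions if d.kind == DELETION]
    assert len(dels) == 1
    d = dels[0]
    assert d.length_nt == 2 and d.frameshifting
    assert d.ref_codon == oracle_deletion_position(reference.cds, nt0, 2) // 3 + 1
    assert all(x.frame_induced for x in rep.disruptions if x.kind == NONSENSE)
    assert not rep.frame_restored


def test_compensating_indels_restore_frame(reference):
    """2-bp deletion followed by a 2-bp insertion ~30 codons later: two
    events, frame restored, still a pseudogene."""
    cds = reference.cds
    del_at, ins_at = 3 * 29, 3 * 59
    mutant = cds[:del_at] + cds[del_at + 2 : ins_at] + "GG" + cds[ins_at:]
    rep = call_disruptions(as_query(mutant), reference)
    assert rep.is_pseudogene
    assert rep.frame_restored
    kinds = sorted(d.kind for d in rep.primary_events() if d.kind != NONSENSE)
    assert kinds == [DELETION, INSERTION]


def test_in_frame_deletion_alone_is_not_pseudogene(reference):
    nt0 = 3 * 49
    mutant = reference.cds[:nt0] + reference.cds[nt0 + 3 :]
    rep = call_disruptions(as_query(mutant), reference)
    assert rep.status == "intact"
    assert [d.kind for d in rep.disruptions] == [DELETION]
    assert rep.disruptions[0].length_nt == 3


def test_nonsense_substitution_called_at_exact_codon(reference):
    c = 100
    nt0 = 3 * (c - 1)
    mutant = reference.cds[:nt0] + "TGA" + reference.cds[nt0 + 3 :]
    rep = call_disruptions(as_query(mutant), reference)
    assert rep.is_pseudogene
    assert [d.signature for d in rep.primary_events()] == [(NONSENSE, c, 0)]
    assert not rep.disruptions[0].frame_induced
    assert rep.first_disruption_fraction == pytest.approx(c / reference.n_codons)


def test_status_invariant_to_synonymous_substitutions(reference):
    """Recoding codons synonymously never flips an intact call."""
    rng = np.random.default_rng(31)
    by_aa = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(translate(codon), []).append(codon)
    codons = [reference.cds[i : i + 3] for i in range(0, len(reference.cds), 3)]
    for idx in rng.choice(range(1, len(codons) - 1), size=40, replace=False):
        options = by_aa[translate(codons[idx])]
        codons[idx] = options[int(rng.integers(len(options)))]
    rep = call_disruptions(as_query("".join(codons)), reference)
    assert rep.status == "intact"


def test_single_edit_mutants_match_oracle(reference):
    """100 random single-event mutants: the reported event equals the
    planted one at its exhaustively-determined leftmost placement."""
    rng = np.random.default_rng(41)
    cds = reference.cds
    for _ in range(100):
        kind = (NONSENSE, DELETION, INSERTION)[int(rng.integers(3))]
        c = int(rng.integers(2, 290))
        nt0 = 3 * (c - 1)
        if kind == NONSENSE:
            stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
            mutant = cds[:nt0] + stop + cds[nt0 + 3 :]
            expected = (NONSENSE, c, 0)
        elif kind == DELETION:
            L = int(rng.integers(1, 13))
            mutant = cds[:nt0] + cds[nt0 + L :]
            pos = oracle_deletion_position(cds, nt0, L)
            expected = (DELETION, pos // 3 + 1, L)
        else:
            L = int(rng.integers(1, 13))
            seg = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=L))
            mutant = cds[:nt0] + seg + cds[nt0:]
            pos = oracle_insertion_position(cds, mutant, L)
            expected = (INSERTION, pos // 3 + 1, L)
        rep = call_disruptions(as_query(mutant), reference)
        indel_like = [d.signature for d in rep.primary_events() if d.kind == expected[0]]
        assert indel_like == [expected], f"planted {expected}, got {rep.disruptions}"
        is_disrupting = kind == NONSENSE or expected[2] % 3 != 0
        assert rep.is_pseudogene == is_disrupting


def test_semiglobal_partial_segment_has_no_end_deletions(reference):
    """A PCR-amplicon-like interior segment must not be charged for its
    missing flanks, and the frame is anchored to the reference grid."""
    cds = reference.cds
    segment = cds[300:1000 + 1]  # not codon-aligned on purpose
    rep = call_disruptions(as_query(segment), reference, semiglobal=True)
    assert rep.status == "intact"
    assert rep.disruptions == ()
    # same segment with a nonsense mutation inside
    c = 150
    nt0 = 3 * (c - 1)
    mutant = cds[:nt0] + "TAA" + cds[nt0 + 3 :]
    rep = call_disruptions(as_query(mutant[300:1001]), reference, semiglobal=True)
    assert [d.signature for d in rep.primary_events()] == [(NONSENSE, c, 0)]


def test_low_identity_query_flagged_not_fabricated(reference, rng):
    """An unrelated sequence is flagged low-confidence (suspect orthology)
    when it falls under the identity threshold.  Gapped global alignment
    of unrelated same-length CDSs pairs up ~60% of columns by chance, so
    a threshold above that level is needed to catch them."""
    unrelated = make_cds(rng, 310)
    rep = call_disruptions(as_query(unrelated), reference, min_identity=0.8)
    assert rep.low_confidence
    assert rep.identity < 0.8
    # a genuine ortholog-level query stays above the default threshold
    rep_self = call_disruptions(as_query(reference.cds), reference)
    assert not rep_self.low_confidence


def test_empty_query_rejected():
    with pytest.raises(ValueError, match="empty"):
        ORSequence(id="q", species="sp", seq="", source="synthetic")


def test_terminal_position_classification(reference):
    n = reference.n_codons
    early = call_disruptions(
        as_query(reference.cds[: 3 * 9] + "TAA" + reference.cds[3 * 10 :]), reference
    )
    assert classify_terminal_position(early) == "five_prime"
    late_codon = 300
    late = call_disruptions(
        as_query(
            reference.cds[: 3 * (late_codon - 1)]
            + "TAA"
            + reference.cds[3 * late_codon :]
        ),
        reference,
    )
    assert late.first_disruption_fraction == pytest.approx(late_codon / n)
    assert classify_terminal_position(late) == "three_prime"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_frameshift_then_many_substitutions_stays_pseudogene(seed):
    """Status is robust to background substitutions around a planted
    frameshift (1-bp deletion)."""
    rng = np.random.default_rng(seed)
    ref = ReferenceProfile(locus="ORX", cds=make_cds(rng, 260))
    cds = ref.cds
    nt0 = 3 * int(rng.integers(2, 250))
    mutant = list(cds[:nt0] + cds[nt0 + 1 :])
    for i in rng.choice(len(mutant), size=10, replace=False):
        mutant[i] = "ACGT"[int(rng.integers(4))]
    rep = call_disruptions(as_query("".join(mutant)), ref)
    assert any(d.frameshifting for d in rep.disruptions)
    assert rep.is_pseudogene
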