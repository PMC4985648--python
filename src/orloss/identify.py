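"""Identification of full-length intact olfactory receptor genes.

Vertebrate OR genes are single-exon, so intactness can be decided on the
nucleotide sequence alone: a candidate is kept when it contains an
uninterrupted ATG..stop open reading frame longer than 250 amino acids
and, after global protein alignment against an intact reference OR, shows
no deletion gap of five or more residues inside a transmembrane (TM)
helix.  Large TM gaps are disqualifying because a receptor missing part
of a membrane-spanning helix cannot fold into a functional
seven-transmembrane protein.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _align
from .pseudogenes import ReferenceProfile
from .sequences import (
    ORSequence,
    STOP_CODONS,
    VALID_ALPHABET,
    reverse_complement,
    translate,
)

REASON_TOO_SHORT = "too_short"
REASON_INTERNAL_STOP = "internal_stop"
REASON_FRAMESHIFT = "frameshift"
REASON_TM_GAP = "tm_gap"
REASON_NO_ORF = "no_orf"
REASON_LOW_IDENTITY = "low_identity"


@dataclass(frozen=True)
class CandidateORF:
    """A maximal ATG..stop open reading frame.

    ``frame`` 0-2 are the three forward frames; 3-5 are frames on the
    reverse complement.  ``start``/``end`` are 0-based half-open
    nucleotide coordinates *in the orientation of the reported frame*
    (i.e. on the reverse complement for frames 3-5), with ``end``
    including the stop codon.  ``aa_length`` counts residues from the
    initiator methionine up to (excluding) the stop.
    """

    frame: int
    start: int
    end: int
    aa_length: int
    translation: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the intact-OR filter.

    ``min_aa_exclusive`` is a strict lower bound: an ORF is kept only if
    it is *longer than* this many amino acids (default 250, so a 250-aa
    ORF is rejected).  ``max_tm_gap_aa`` is the largest tolerated
    deletion inside a TM interval (default 4: gaps of >= 5 aa reject).
    ``min_identity`` optionally enables a protein-similarity prefilter
    (fraction of identical residues over aligned columns); ``None``
    disables it (the default).
    """

    min_aa_exclusive: int = 250
    max_tm_gap_aa: int = 4
    min_identity: float | None = None


@dataclass(frozen=True)
class FilterDecision:
    verdict: str  # "intact" | "rejected"
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.verdict == "intact") != (len(self.reasons) == 0):
            raise ValueError("verdict 'intact' iff reasons empty")

    @property
    def intact(self) -> bool:
        return self.verdict == "intact"


def _orfs_in_strand(seq: str, frame_offset: int, frame_label: int) -> list[CandidateORF]:
    orfs = []
    start = None
    for pos in range(frame_offset, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if start is not None:
                cds = seq[start:pos]
                orfs.append(
                    CandidateORF(
                        frame=frame_label,
                        start=start,
                        end=pos + 3,
                        aa_length=len(cds) // 3,
                        translation=translate(cds),
                    )
                )
                start = None
        elif codon == "ATG" and start is None:
            # leftmost ATG after the previous stop => maximal ORF
            start = pos
    return orfs


def find_orfs(seq: ORSequence | str) -> list[CandidateORF]:
    """Enumerate every maximal ATG-to-stop ORF in all six frames.

    Maximal means the ORF cannot be extended 5': its ATG is the first
    start codon after the preceding in-frame stop.  Codons containing N
    translate to X and never count as start or stop codons.  Results are
    sorted by decreasing amino-acid length, ties broken by (frame, start).
    """
    nt = seq.seq if isinstance(seq, ORSequence) else seq
    bad = set(nt) - VALID_ALPHABET
    if bad:
        raise ValueError(f"sequence contains characters outside ACGTN: {sorted(bad)}")
    if len(nt) < 6:
        raise ValueError("sequence shorter than 6 nt cannot contain an ORF")
    orfs: list[CandidateORF] = []
    rc = reverse_complement(nt)
    for off in range(3):
        orfs.extend(_orfs_in_strand(nt, off, off))
        orfs.extend(_orfs_in_strand(rc, off, off + 3))
    orfs.sort(key=lambda o: (-o.aa_length, o.frame, o.start))
    return orfs


def _deletion_runs(target_row: str, query_row: str) -> list[tuple[int, int]]:
    """0-based half-open reference-residue spans deleted from the query."""
    runs = []
    ref_pos = 0
    run_start = None
    for tc, qc in zip(target_row, query_row):
        if tc == "-":
            continue
        if qc == "-":
            if run_start is None:
                run_start = ref_pos
        else:
            if run_start is not None:
                runs.append((run_start, ref_pos))
                run_start = None
        ref_pos += 1
    if run_start is not None:
        runs.append((run_start, ref_pos))
    return runs


def filter_intact(
    orf: CandidateORF,
    reference: ReferenceProfile,
    criteria: FilterCriteria = FilterCriteria(),
) -> FilterDecision:
    """Apply the length and TM-gap filters to a candidate ORF.

    The ORF's translation is globally aligned to the reference OR
    protein; a deletion run of more than ``max_tm_gap_aa`` residues that
    overlaps any TM interval rejects the candidate.  All failed criteria
    are reported, not just the first.
    """
    reasons: list[str] = []
    if orf.aa_length <= criteria.min_aa_exclusive:
        reasons.append(REASON_TOO_SHORT)

    aligner = _align.protein_aligner()
    alignment = aligner.align(reference.protein, orf.translation)[0]
    target_row, query_row = _align.gapped_rows(alignment)

    if criteria.min_identity is not None:
        cols = sum(1 for t, q in zip(target_row, query_row) if t != "-" and q != "-")
        ident = (
            sum(1 for t, q in zip(target_row, query_row) if t == q and t != "-") / cols
            if cols
            else 0.0
        )
        if ident < criteria.min_identity:
            reasons.append(REASON_LOW_IDENTITY)

    tm_spans = [(s - 1, e) for s, e in reference.tm_intervals]  # 1-based incl -> 0-based half-open
    for run_start, run_end in _deletion_runs(target_row, query_row):
        if run_end - run_start <= criteria.max_tm_gap_aa:
            continue
        if any(run_start < e and s < run_end for s, e in tm_spans):
            reasons.append(REASON_TM_GAP)
            break

    verdict = "intact" if not reasons else "rejected"
    return FilterDecision(verdict=verdict, reasons=tuple(reasons))


def classify_sequence(
    seq: ORSequence,
    reference: ReferenceProfile,
    criteria: FilterCriteria = FilterCriteria(),
    expect_full_cds: bool = False,
) -> tuple[CandidateORF | None, FilterDecision]:
    """Classify a raw candidate sequence as intact OR or rejected.

    The default path searches all six frames for the longest maximal ORF
    and filters it.  With ``expect_full_cds`` the sequence itself is
    treated as a putative CDS, and structural defects are named
    explicitly: a length not divisible by 3 is reported as a frameshift
    and interior stop codons as internal stops.
    """
    if expect_full_cds:
        nt = seq.seq
        reasons = []
        if len(nt) % 3 != 0:
            reasons.append(REASON_FRAMESHIFT)
        prot = translate(nt[: len(nt) - len(nt) % 3])
        body = prot[:-1] if prot.endswith("*") else prot
        if not nt.startswith("ATG"):
            reasons.append(REASON_NO_ORF)
        if "*" in body:
            reasons.append(REASON_INTERNAL_STOP)
        if reasons:
            return None, FilterDecision(verdict="rejected", reasons=tuple(reasons))
        orf = CandidateORF(
            frame=0, start=0, end=len(nt), aa_length=len(body), translation=body
        )
        return orf, filter_intact(orf, reference, criteria)

    try:
        orfs = find_orfs(seq)
    except ValueError:
        return None, FilterDecision(verdict="rejected", reasons=(REASON_NO_ORF,))
    if not orfs:
        return None, FilterDecision(verdict="rejected", reasons=(REASON_NO_ORF,))
    best = orfs[0]
    return best, filter_intact(best, reference, criteria)
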