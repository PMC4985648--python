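"""Codon-aware pseudogene calling against an intact ortholog reference.

A query sequence is globally aligned (affine gaps) to the intact
reference CDS of its locus and the alignment is projected onto reference
codons.  Indels whose length is not a multiple of 3 shift the reading
frame; stop codons are read in the *running* frame of the query, so
stops induced downstream of a frameshift are detected and reported (they
are flagged ``frame_induced`` to distinguish them from point nonsense
mutations).  A query is a pseudogene when it carries at least one
nonsense codon or one frameshifting indel; in-frame indels are recorded
but are not by themselves disqualifying.

Indel coordinates are left-normalized (shifted to their 5'-most
equivalent placement on the reference, as in VCF left alignment) so that
reported positions are well-defined when several equal-scoring
placements exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import _align
from .sequences import ORSequence, STOP_CODONS, is_valid_cds, translate

logger = logging.getLogger(__name__)

NONSENSE = "nonsense"
INSERTION = "insertion"
DELETION = "deletion"

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
NONE = "none"


@dataclass(frozen=True)
class ReferenceProfile:
    """Intact reference CDS for one locus.

    ``tm_intervals`` are 1-based inclusive codon intervals of the seven
    transmembrane helices on this reference (may be empty when only
    disruption calling, not the TM-gap filter, is needed).
    """

    locus: str
    cds: str
    tm_intervals: tuple[tuple[int, int], ...] = ()
    species: str | None = None

    def __post_init__(self) -> None:
        if not is_valid_cds(self.cds):
            raise ValueError(
                f"reference CDS for locus {self.locus!r} is not an intact ORF"
            )
        ivals = list(self.tm_intervals)
        if any(s > e or s < 1 for s, e in ivals):
            raise ValueError("malformed TM interval")
        if ivals != sorted(ivals) or any(
            a_end >= b_start for (_, a_end), (b_start, _) in zip(ivals, ivals[1:])
        ):
            raise ValueError("TM intervals must be sorted and non-overlapping")

    @property
    def n_codons(self) -> int:
        """Codon count of the CDS including the terminal stop codon."""
        return len(self.cds) // 3

    @property
    def protein(self) -> str:
        """Translation without the terminal stop."""
        return translate(self.cds)[:-1]


@dataclass(frozen=True)
class Disruption:
    """One ORF-disrupting (or in-frame indel) event on the reference frame.

    ``ref_codon`` is the 1-based reference codon of the event after left
    normalization; ``length_nt`` is 0 for nonsense codons.  For nonsense
    events ``frame_induced`` marks stop codons that arise downstream of
    an uncompensated frameshift rather than from a point substitution.
    """

    kind: str
    ref_codon: int
    length_nt: int = 0
    query_pos: int = 0
    frame_induced: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (NONSENSE, INSERTION, DELETION):
            raise ValueError(f"unknown disruption kind {self.kind!r}")
        if self.ref_codon < 1:
            raise ValueError("ref_codon must be >= 1")
        if self.kind in (INSERTION, DELETION) and self.length_nt < 1:
            raise ValueError("indels require length_nt >= 1")

    @property
    def frameshifting(self) -> bool:
        return self.kind in (INSERTION, DELETION) and self.length_nt % 3 != 0

    @property
    def disrupting(self) -> bool:
        return self.kind == NONSENSE or self.frameshifting

    @property
    def signature(self) -> tuple[str, int, int]:
        return (self.kind, self.ref_codon, self.length_nt)


@dataclass(frozen=True)
class DisruptionReport:
    query_id: str
    locus: str
    disruptions: tuple[Disruption, ...]
    status: str  # "intact" | "pseudogene"
    first_disruption_fraction: float | None
    frame_restored: bool
    identity: float
    low_confidence: bool = False
    species: str | None = None

    @property
    def is_pseudogene(self) -> bool:
        return self.status == "pseudogene"

    def primary_events(self) -> tuple[Disruption, ...]:
        """Events excluding frame-induced secondary stop codons."""
        return tuple(d for d in self.disruptions if not d.frame_induced)


# ---------------------------------------------------------------------------
# alignment projection


@dataclass
class _Indel:
    kind: str
    ref_start: int  # 0-based nt position on reference
    length: int
    q_pos: int  # 0-based nt offset in query (first deleted-adjacent / inserted base)


def _collect_edits(target_row: str, query_row: str) -> tuple[list[_Indel], list[int | None], int, int]:
    """Walk alignment columns.

    Returns (indels, ref_position_of_each_query_base, matches, aligned_columns).
    """
    edits: list[_Indel] = []
    ref_at_q: list[int | None] = []
    r = q = 0
    matches = cols = 0
    cur: _Indel | None = None
    for tc, qc in zip(target_row, query_row):
        if tc == "-" and qc == "-":
            continue
        if qc == "-":  # deletion from query
            if cur is None or cur.kind != DELETION or cur.ref_start + cur.length != r:
                cur = _Indel(DELETION, r, 0, q)
                edits.append(cur)
            cur.length += 1
            r += 1
        elif tc == "-":  # insertion into query
            if cur is None or cur.kind != INSERTION or cur.q_pos + cur.length != q:
                cur = _Indel(INSERTION, r, 0, q)
                edits.append(cur)
            cur.length += 1
            ref_at_q.append(None)
            q += 1
        else:
            cur = None
            cols += 1
            if tc == qc:
                matches += 1
            ref_at_q.append(r)
            r += 1
            q += 1
    return edits, ref_at_q, matches, cols


def left_normalize_deletion(ref: str, start: int, length: int, limit: int = 0) -> int:
    """5'-most equivalent start of deleting ``ref[start:start+length]``."""
    while start > limit and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def left_normalize_insertion(ref: str, segment: str, pos: int, limit: int = 0) -> tuple[int, str]:
    """5'-most equivalent (position, segment) for inserting ``segment`` before ``ref[pos]``."""
    while pos > limit and segment and segment[-1] == ref[pos - 1]:
        segment = ref[pos - 1] + segment[:-1]
        pos -= 1
    return pos, segment


def _normalize_edits(edits: list[_Indel], ref: str, query: str) -> list[_Indel]:
    out: list[_Indel] = []
    prev_ref_end = 0
    for e in edits:
        if e.kind == DELETION:
            start = left_normalize_deletion(ref, e.ref_start, e.length, prev_ref_end)
            shift = e.ref_start - start
            out.append(_Indel(DELETION, start, e.length, max(e.q_pos - shift, 0)))
            prev_ref_end = start + e.length
        else:
            seg = query[e.q_pos : e.q_pos + e.length]
            pos, _seg = left_normalize_insertion(ref, seg, e.ref_start, prev_ref_end)
            shift = e.ref_start - pos
            out.append(_Indel(INSERTION, pos, e.length, max(e.q_pos - shift, 0)))
            prev_ref_end = pos
    return out


def _merge_near_indel_pairs(edits: list[_Indel], window_nt: int = 9) -> list[_Indel]:
    """Complex-variant normalization: an insertion and a deletion within
    ``window_nt`` of each other on the reference are re-expressed as their
    net edit (a block substitution when lengths are equal, else one net
    indel).  Parsimony alignment of clustered substitutions can otherwise
    fabricate compensating short indel pairs.
    """
    changed = True
    while changed:
        changed = False
        for i in range(len(edits) - 1):
            e1, e2 = edits[i], edits[i + 1]
            if {e1.kind, e2.kind} != {INSERTION, DELETION}:
                continue
            e1_ref_end = e1.ref_start + (e1.length if e1.kind == DELETION else 0)
            if e2.ref_start - e1_ref_end > window_nt:
                continue
            ins_len = e1.length if e1.kind == INSERTION else e2.length
            del_len = e1.length if e1.kind == DELETION else e2.length
            net = ins_len - del_len
            merged: list[_Indel] = []
            if net > 0:
                merged = [_Indel(INSERTION, e1.ref_start, net, e1.q_pos)]
            elif net < 0:
                merged = [_Indel(DELETION, e1.ref_start, -net, e1.q_pos)]
            edits = edits[:i] + merged + edits[i + 2 :]
            changed = True
            break
    return edits


def _mapping_from_edits(
    edits: list[_Indel], ref_len: int, query_len: int, ref_offset: int = 0
) -> list[int | None]:
    """Rebuild the query-base -> reference-position map implied by an edit
    list (1:1 outside edits, starting at ``ref_offset`` for partial queries)."""
    ref_at_q: list[int | None] = []
    r = ref_offset
    q = 0
    for e in sorted(edits, key=lambda e: (e.ref_start, e.kind == DELETION)):
        while r < e.ref_start and q < query_len:
            ref_at_q.append(r)
            r += 1
            q += 1
        if e.kind == INSERTION:
            take = min(e.length, query_len - q)
            ref_at_q.extend([None] * take)
            q += take
        else:
            r += e.length
    while q < query_len and r < ref_len:
        ref_at_q.append(r)
        r += 1
        q += 1
    while len(ref_at_q) < query_len:
        ref_at_q.append(None)
    return ref_at_q


def _scan_stops(
    query: str,
    ref_at_q: list[int | None],
    n_codons: int,
    frame_anchor: int,
) -> list[Disruption]:
    """Find stop codons reading the query in its running frame.

    ``frame_anchor`` is the query offset of the first complete codon
    (0 for full-length queries; derived from the first aligned reference
    position for partial segments).  A stop is a point nonsense mutation
    when its three bases map onto one reference codon in reference frame
    (consecutive reference positions starting on a codon boundary);
    otherwise it is flagged as frame-induced.
    """
    stops: list[Disruption] = []
    for i in range(frame_anchor, len(query) - 2, 3):
        codon = query[i : i + 3]
        if codon not in STOP_CODONS:
            continue
        refs = ref_at_q[i : i + 3]
        mapped = [r for r in refs if r is not None]
        if not mapped:
            continue
        clean = (
            len(mapped) == 3
            and mapped[1] == mapped[0] + 1
            and mapped[2] == mapped[0] + 2
            and mapped[0] % 3 == 0
        )
        ref_codon = mapped[0] // 3 + 1
        if ref_codon >= n_codons:
            # maps onto (or beyond) the reference's own terminal stop codon
            continue
        stops.append(
            Disruption(
                kind=NONSENSE,
                ref_codon=ref_codon,
                length_nt=0,
                query_pos=i,
                frame_induced=not clean,
            )
        )
    return stops


def call_disruptions(
    query: ORSequence,
    reference: ReferenceProfile,
    semiglobal: bool = False,
    min_identity: float = 0.5,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -2.0,
) -> DisruptionReport:
    """Detect ORF-disrupting mutations in ``query`` relative to ``reference``.

    Set ``semiglobal`` for partial gene segments (e.g. PCR amplicons):
    end gaps of the query are then unpenalized and not reported as
    deletions, and the reading frame is anchored to the reference codon
    grid at the first aligned position.

    A query whose nucleotide identity to the reference falls below
    ``min_identity`` is flagged ``low_confidence`` (orthology suspect);
    its events are still reported but should not be trusted.
    """
    if not query.seq:
        raise ValueError("empty query")
    ref = reference.cds
    aligner = _align.nucleotide_aligner(
        match=match,
        mismatch=mismatch,
        gap_open=gap_open,
        gap_extend=gap_extend,
        free_query_end_gaps=semiglobal,
    )
    alignment = aligner.align(ref, query.seq)[0]
    target_row, query_row = _align.gapped_rows(alignment)
    edits, ref_at_q, matches, cols = _collect_edits(target_row, query_row)

    if semiglobal:
        # leading/trailing deletion runs are missing flanks, not events
        if edits and edits[0].kind == DELETION and edits[0].ref_start == 0 and edits[0].q_pos == 0:
            edits = edits[1:]
        if edits and edits[-1].kind == DELETION and edits[-1].ref_start + edits[-1].length == len(ref):
            edits = edits[:-1]

    edits = _normalize_edits(edits, ref, query.seq)
    edits = _merge_near_indel_pairs(edits)
    edits = _normalize_edits(edits, ref, query.seq)

    events: list[Disruption] = [
        Disruption(
            kind=e.kind,
            ref_codon=e.ref_start // 3 + 1,
            length_nt=e.length,
            query_pos=e.q_pos,
        )
        for e in edits
    ]

    first_ref = next((r for r in ref_at_q if r is not None), 0)
    frame_anchor = 0
    if semiglobal:
        first_q = next((q for q, r in enumerate(ref_at_q) if r is not None), 0)
        frame_anchor = first_q + (-first_ref) % 3
    # stop codons are read against the mapping implied by the final
    # (normalized, complexity-merged) edit list
    final_map = _mapping_from_edits(
        edits, len(ref), len(query.seq), first_ref if semiglobal else 0
    )
    events.extend(_scan_stops(query.seq, final_map, reference.n_codons, frame_anchor))
    events.sort(key=lambda d: (d.ref_codon, d.query_pos, d.kind))

    identity = matches / cols if cols else 0.0
    low_confidence = identity < min_identity
    if low_confidence:
        logger.warning(
            "query %s has %.1f%% identity to reference %s (< %.0f%%); "
            "orthology suspect, report flagged low-confidence",
            query.id, 100 * identity, reference.locus, 100 * min_identity,
        )

    disrupting = [d for d in events if d.disrupting]
    status = "pseudogene" if disrupting else "intact"
    first_fraction = (
        disrupting[0].ref_codon / reference.n_codons if disrupting else None
    )
    net = sum(
        d.length_nt if d.kind == INSERTION else -d.length_nt
        for d in events
        if d.kind in (INSERTION, DELETION)
    )
    frame_restored = any(d.frameshifting for d in events) and net % 3 == 0

    return DisruptionReport(
        query_id=query.id,
        locus=reference.locus,
        disruptions=tuple(events),
        status=status,
        first_disruption_fraction=first_fraction,
        frame_restored=frame_restored,
        identity=identity,
        low_confidence=low_confidence,
        species=query.species,
    )


def classify_terminal_position(
    report: DisruptionReport, threshold_fraction: float = 0.5
) -> str:
    """Classify where along the gene the first disruption falls.

    ``five_prime`` when the first ORF-disrupting event lies in the 5'
    portion of the reference (fraction < threshold), ``three_prime``
    otherwise, ``none`` for intact reports.  Early (5') disruptions
    truncate most transmembrane domains and are the strongest evidence
    of nonfunctionality.
    """
    if report.first_disruption_fraction is None:
        return NONE
    return (
        FIVE_PRIME
        if report.first_disruption_fraction < threshold_fraction
        else THREE_PRIME
    )
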