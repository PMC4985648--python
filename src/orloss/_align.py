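"""Shared pairwise-alignment helpers (thin wrappers over Bio.Align).

Gap cost convention follows Biopython: a gap of length L costs
``open + (L - 1) * extend`` (the opening position is charged the open
score, subsequent positions the extend score).
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices


def nucleotide_aligner(
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -8.0,
    gap_extend: float = -2.0,
    free_query_end_gaps: bool = False,
) -> Align.PairwiseAligner:
    """Global nucleotide aligner with affine gaps.

    With ``free_query_end_gaps`` the alignment is semiglobal for the query:
    missing query flanks (gap runs in the query row at either end) are not
    penalized, which is appropriate for partial gene segments such as
    PCR amplicons.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if free_query_end_gaps:
        # "deletions" in Biopython's nomenclature are target letters absent
        # from the query, i.e. gaps in the query row.
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    return aligner


def protein_aligner(
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    matrix: str = "BLOSUM62",
) -> Align.PairwiseAligner:
    """Global protein aligner with affine gaps and a BLOSUM substitution matrix."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def gapped_rows(alignment) -> tuple[str, str]:
    """Return (target_row, query_row) as gapped strings."""
    return str(alignment[0]), str(alignment[1])
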