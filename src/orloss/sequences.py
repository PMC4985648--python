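"""Core sequence types and codon-level helpers.

Olfactory receptor (OR) genes are single-exon, so a candidate locus is a
plain nucleotide string and the coding sequence is an uninterrupted
ATG..stop open reading frame.  Everything downstream (ORF finding,
pseudogene calling, simulation) works on these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
VALID_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset(unambiguous_dna_by_id[1].stop_codons)  # TAA, TAG, TGA
_CODON_TABLE = dict(unambiguous_dna_by_id[1].forward_table)
SENSE_CODONS = tuple(sorted(_CODON_TABLE))

SOURCES = ("genome", "resequenced", "synthetic")


@dataclass(frozen=True)
class ORSequence:
    """One candidate olfactory receptor nucleotide sequence.

    Parameters
    ----------
    id :
        Unique record identifier (FASTA header up to first whitespace).
    species :
        Species the sequence was obtained from.
    seq :
        Nucleotide sequence over the alphabet ``{A, C, G, T, N}``.
    locus :
        Optional locus / ortholog-group label (e.g. ``"OR09"``).
    source :
        Provenance: ``genome`` (assembly-derived), ``resequenced``
        (PCR amplicon, possibly a partial gene segment) or ``synthetic``.
    """

    id: str
    species: str
    seq: str
    locus: str | None = None
    source: str = "genome"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_codon(codon: str) -> str:
    """Translate one codon; codons containing N give 'X', stops give '*'."""
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return _CODON_TABLE[codon]


def translate(seq: str) -> str:
    """Translate a nucleotide string codon-by-codon (trailing partial codon ignored)."""
    return "".join(
        translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def is_valid_cds(seq: str) -> bool:
    """True for an intact CDS: ATG start, terminal stop, no internal stop, length % 3 == 0."""
    if len(seq) % 3 != 0 or len(seq) < 6:
        return False
    if not seq.startswith("ATG") or seq[-3:] not in STOP_CODONS:
        return False
    return all(
        seq[i : i + 3] not in STOP_CODONS for i in range(0, len(seq) - 3, 3)
    )
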