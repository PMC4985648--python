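"""Readers and writers for the pipeline's plain-text formats.

FASTA headers use ``|``-delimited fields: ``species|locus`` (two fields,
the simulator's convention) or ``id|species|locus``; a plain header is
kept as both id and species.  Tables are tab-separated with a header
row.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orthologs import OrthologGroup
from .pseudogenes import Disruption, DisruptionReport, ReferenceProfile
from .sequences import ORSequence
from .shared import LossAssignment
from .simulate import TruthLabels

logger = logging.getLogger(__name__)


# -- FASTA ------------------------------------------------------------------


def _parse_header(token: str) -> tuple[str, str | None]:
    """(species, locus) from a ``|``-delimited FASTA id."""
    parts = token.split("|")
    if len(parts) == 2:
        return parts[0], parts[1]
    if len(parts) >= 3:
        return parts[1], parts[2]
    return token, None


def read_fasta(path: str | Path, source: str = "genome") -> list[ORSequence]:
    """Read FASTA records into :class:`ORSequence` objects.

    Raises on duplicate ids and on malformed leading content (with the
    offending line number); an empty file yields an empty list with a
    warning.  CRLF and LF line endings parse identically.
    """
    path = Path(path)
    with open(path, newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: malformed FASTA (expected '>' header, "
                    f"got {line.strip()[:30]!r})"
                )
            break

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("FASTA file %s is empty", path)
        return []
    seen: set[str] = set()
    out: list[ORSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        species, locus = _parse_header(rec.id)
        out.append(
            ORSequence(
                id=rec.id,
                species=species,
                locus=locus,
                seq=str(rec.seq).upper(),
                source=source,
            )
        )
    return out


def write_fasta(seqs: list[ORSequence], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns; ids round-trip through
    :func:`read_fasta`."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# -- TSV helpers ------------------------------------------------------------


def _write_tsv(path: str | Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        rows = [row for row in r if row]
    if not rows:
        return [], []
    return rows[0], rows[1:]


# -- reference panel --------------------------------------------------------


def read_tm_intervals(path: str | Path) -> dict[str, tuple[tuple[int, int], ...]]:
    """TSV ``locus tm_index start_codon end_codon`` -> per-locus intervals."""
    header, rows = _read_tsv(path)
    acc: dict[str, list[tuple[int, tuple[int, int]]]] = {}
    for locus, idx, start, end in rows:
        acc.setdefault(locus, []).append((int(idx), (int(start), int(end))))
    return {
        locus: tuple(iv for _, iv in sorted(ivals)) for locus, ivals in acc.items()
    }


def write_tm_intervals(
    intervals: dict[str, tuple[tuple[int, int], ...]], path: str | Path
) -> None:
    rows = [
        [locus, i + 1, s, e]
        for locus in sorted(intervals)
        for i, (s, e) in enumerate(intervals[locus])
    ]
    _write_tsv(path, ["locus", "tm_index", "start_codon", "end_codon"], rows)


def read_reference_panel(
    fasta_path: str | Path, tm_path: str | Path | None = None
) -> dict[str, ReferenceProfile]:
    """Reference panel: FASTA of intact CDSs (id = locus, or species|locus)
    plus an optional TM-interval TSV."""
    tm = read_tm_intervals(tm_path) if tm_path else {}
    panel: dict[str, ReferenceProfile] = {}
    for rec in read_fasta(fasta_path):
        locus = rec.locus or rec.id
        panel[locus] = ReferenceProfile(
            locus=locus,
            cds=rec.seq,
            tm_intervals=tm.get(locus, ()),
            species=rec.species if rec.locus else None,
        )
    return panel


# -- groups / aliases / labels ----------------------------------------------


def read_group_table(path: str | Path) -> dict[str, str]:
    """TSV ``species group`` -> mapping."""
    _, rows = _read_tsv(path)
    return {sp: grp for sp, grp in rows}


def read_alias_table(path: str | Path) -> dict[str, str]:
    """TSV ``sequenced_species genome_species`` -> congener alias map."""
    _, rows = _read_tsv(path)
    return {a: b for a, b in rows}


def write_truth_labels(labels: TruthLabels, path: str | Path) -> None:
    rows = [
        [sp, locus, labels.status[(sp, locus)]]
        for sp, locus in sorted(labels.status)
    ]
    _write_tsv(path, ["species", "locus", "status"], rows)


def read_classifications(path: str | Path) -> dict[tuple[str, str], str]:
    _, rows = _read_tsv(path)
    return {(sp, locus): status for sp, locus, status in rows}


# -- disruption reports ------------------------------------------------------


def write_reports_tsv(reports: list[DisruptionReport], path: str | Path) -> None:
    rows = []
    for r in sorted(reports, key=lambda r: (r.locus, r.query_id)):
        ev = ";".join(
            f"{d.kind}:{d.ref_codon}:{d.length_nt}" for d in r.disruptions
        )
        rows.append(
            [
                r.query_id,
                r.species or "",
                r.locus,
                r.status,
                len(r.disruptions),
                "" if r.first_disruption_fraction is None
                else f"{r.first_disruption_fraction:.4f}",
                int(r.frame_restored),
                f"{r.identity:.4f}",
                int(r.low_confidence),
                ev,
            ]
        )
    _write_tsv(
        path,
        ["query", "species", "locus", "status", "n_disruptions",
         "first_fraction", "frame_restored", "identity", "low_confidence", "events"],
        rows,
    )


def write_events_tsv(reports: list[DisruptionReport], path: str | Path) -> None:
    """Long-format per-event table."""
    rows = [
        [r.query_id, r.species or "", r.locus, d.kind, d.ref_codon,
         d.length_nt, d.query_pos, int(d.frame_induced)]
        for r in sorted(reports, key=lambda r: (r.locus, r.query_id))
        for d in r.disruptions
    ]
    _write_tsv(
        path,
        ["query", "species", "locus", "kind", "ref_codon", "length_nt",
         "query_pos", "frame_induced"],
        rows,
    )


def read_reports_tsv(path: str | Path, events_path: str | Path) -> list[DisruptionReport]:
    """Rebuild reports from the summary + long-format event tables."""
    _, ev_rows = _read_tsv(events_path)
    ev_by_query: dict[str, list[Disruption]] = {}
    for query, _sp, _locus, kind, ref_codon, length_nt, query_pos, induced in ev_rows:
        ev_by_query.setdefault(query, []).append(
            Disruption(
                kind=kind,
                ref_codon=int(ref_codon),
                length_nt=int(length_nt),
                query_pos=int(query_pos),
                frame_induced=bool(int(induced)),
            )
        )
    _, rows = _read_tsv(path)
    out = []
    for (query, species, locus, status, _n, first_frac, restored,
         identity, lowconf, _ev) in rows:
        out.append(
            DisruptionReport(
                query_id=query,
                locus=locus,
                disruptions=tuple(ev_by_query.get(query, [])),
                status=status,
                first_disruption_fraction=float(first_frac) if first_frac else None,
                frame_restored=bool(int(restored)),
                identity=float(identity),
                low_confidence=bool(int(lowconf)),
                species=species or None,
            )
        )
    return out


# -- ortholog groups / shared events -----------------------------------------


def write_groups_tsv(groups: list[OrthologGroup], path: str | Path) -> None:
    rows = [
        [g.group_id, f"{g.support:g}", sp, gene]
        for g in groups
        for sp, gene in sorted(g.members.items())
    ]
    _write_tsv(path, ["group_id", "support", "species", "gene"], rows)


def write_loss_tsv(assignments: list[LossAssignment], path: str | Path) -> None:
    rows = []
    for a in sorted(assignments, key=lambda a: a.locus):
        for call in a.ancestral_calls:
            sigs = ";".join(f"{k}:{c}:{L}" for k, c, L in call.signatures)
            rows.append(
                [a.locus, call.branch, ",".join(sorted(call.species)),
                 call.evidence, sigs]
            )
        for t in a.terminal_events:
            k, c, L = t.signature
            rows.append([a.locus, t.species, t.species, "terminal", f"{k}:{c}:{L}"])
    _write_tsv(path, ["locus", "branch", "species", "evidence", "signatures"], rows)
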