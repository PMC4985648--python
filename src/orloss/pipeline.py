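"""End-to-end pipeline: simulate -> identify -> tree -> orthologs -> call
-> shared -> stats -> report.

The pipeline is configured by a flat :class:`PipelineConfig` (loadable
from YAML; unknown keys are rejected) and emits per-stage TSVs plus a
machine-readable ``summary.json``.  With ``simulate`` enabled it runs on
a synthetic waterbird repertoire with known truth; otherwise it consumes
user-supplied FASTA files, a reference panel, a species tree and a group
table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .identify import FilterCriteria, classify_sequence
from .orthologs import OrthologCriteria, build_gene_tree, extract_ortholog_clades
from .pseudogenes import call_disruptions
from .sequences import ORSequence
from .shared import SpeciesTree, find_shared_disruptions, infer_ancestral_loss
from .simulate import PENGUIN_SPECIES, simulate_repertoire, waterbird_scenario
from .stats import contingency_table, fisher_exact

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of every pipeline stage."""

    outdir: str = "orloss_out"
    seed: int = 0
    log_level: str = "INFO"

    # simulate stage (synthetic waterbird scenario)
    simulate: bool = True
    n_loci: int = 29
    codon_length: int = 310
    substitution_rate: float = 0.02
    with_absence: bool = True

    # external inputs (used when simulate is false)
    input_fastas: list[str] = field(default_factory=list)
    reference_fasta: str | None = None
    tm_tsv: str | None = None
    species_tree_newick: str | None = None
    groups_tsv: str | None = None
    aliases_tsv: str | None = None

    # identify stage
    min_aa: int = 250
    tm_gap: int = 4

    # tree + ortholog stages (optional; NJ plumbing on intact sequences)
    run_tree: bool = False
    n_bootstrap: int = 100
    min_support: float = 85.0
    min_species: int = 4

    # pseudogene calling
    min_identity: float = 0.5
    semiglobal: bool = False

    # shared disruptions / ancestral loss
    tolerance: int = 0
    weak_min_inframe_nt: int = 12

    # stats
    group1: str = "penguin"
    group2: str = "non_penguin"

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 1:
            raise ValueError("min_identity outside [0, 1]")
        if self.tolerance < 0 or self.n_bootstrap < 0:
            raise ValueError("tolerance and n_bootstrap must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the summary dict.

    Writes per-stage TSVs and ``summary.json`` under ``config.outdir``.
    Bit-reproducible for a fixed config and seed.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "orloss_version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }

    aliases: dict[str, str] = {}

    # -- inputs ------------------------------------------------------------
    if config.simulate:
        sim_cfg = waterbird_scenario(
            seed=config.seed,
            n_loci=config.n_loci,
            codon_length=config.codon_length,
            substitution_rate=config.substitution_rate,
            with_absence=config.with_absence,
        )
        result = simulate_repertoire(sim_cfg)
        sequences = result.sequences
        references = result.references
        species_tree = sim_cfg.species_tree
        groups = {
            sp: (config.group1 if sp in PENGUIN_SPECIES else config.group2)
            for sp in species_tree.species
        }
        by_species: dict[str, list[ORSequence]] = {}
        for s in sequences:
            by_species.setdefault(s.species, []).append(s)
        for sp, seqs in sorted(by_species.items()):
            io.write_fasta(seqs, outdir / f"{sp}.fasta")
        io.write_truth_labels(result.labels, outdir / "truth_labels.tsv")
        io.write_fasta(
            [
                ORSequence(id=loc, species=r.species or "ancestor", locus=loc,
                           seq=r.cds, source="synthetic")
                for loc, r in sorted(references.items())
            ],
            outdir / "references.fasta",
        )
        io.write_tm_intervals(
            {loc: r.tm_intervals for loc, r in references.items()},
            outdir / "references_tm.tsv",
        )
        with open(outdir / "true_gene_trees.nwk", "w") as fh:
            for loc in sorted(result.gene_trees):
                fh.write(result.gene_trees[loc] + "\n")
        summary["stages"]["simulate"] = {
            "n_sequences": len(sequences),
            "n_loci": config.n_loci,
            "n_species": len(species_tree.species),
            "n_absent": sum(
                1 for st in result.labels.status.values() if st == "absent"
            ),
            "n_planted_events": len(result.labels.planted),
        }
        truth_labels = result.labels
    else:
        missing = [
            name
            for name, val in [
                ("input_fastas", config.input_fastas),
                ("reference_fasta", config.reference_fasta),
                ("species_tree_newick", config.species_tree_newick),
                ("groups_tsv", config.groups_tsv),
            ]
            if not val
        ]
        if missing:
            raise ValueError(
                f"simulate is disabled but required inputs are missing: {missing}"
            )
        sequences = [
            s for p in config.input_fastas for s in io.read_fasta(p)
        ]
        references = io.read_reference_panel(config.reference_fasta, config.tm_tsv)
        with open(config.species_tree_newick) as fh:
            species_tree = SpeciesTree.from_newick(fh.read())
        groups = io.read_group_table(config.groups_tsv)
        if config.aliases_tsv:
            aliases = io.read_alias_table(config.aliases_tsv)
        truth_labels = None

    no_locus = [s.id for s in sequences if not s.locus or s.locus not in references]
    if no_locus:
        raise ValueError(
            "sequences without a reference locus (expected 'species|locus' "
            f"headers matching the reference panel): {no_locus[:5]}"
        )

    # -- identify ----------------------------------------------------------
    criteria = FilterCriteria(
        min_aa_exclusive=config.min_aa, max_tm_gap_aa=config.tm_gap
    )
    verdict_rows = []
    intact_seqs: list[ORSequence] = []
    for s in sequences:
        orf, decision = classify_sequence(s, references[s.locus], criteria)
        if decision.intact:
            intact_seqs.append(s)
        verdict_rows.append(
            [s.id, s.species, decision.verdict, ",".join(decision.reasons),
             orf.aa_length if orf else 0, orf.frame if orf else ""]
        )
    io._write_tsv(
        outdir / "identify.tsv",
        ["id", "species", "verdict", "reasons", "aa_length", "frame"],
        verdict_rows,
    )
    summary["stages"]["identify"] = {
        "n_candidates": len(sequences),
        "n_intact": len(intact_seqs),
    }

    # -- tree + orthologs (optional plumbing on equal-length intact seqs) ---
    if config.run_tree:
        widths = {len(s.seq) for s in intact_seqs}
        if len(widths) == 1 and len(intact_seqs) >= 3:
            tree = build_gene_tree(
                [(s.id, s.seq) for s in intact_seqs],
                n_bootstrap=config.n_bootstrap,
                seed=config.seed,
            )
            tree.root()
            ortho = extract_ortholog_clades(
                tree,
                OrthologCriteria(
                    min_support_exclusive=config.min_support,
                    min_species=config.min_species,
                ),
            )
            with open(outdir / "gene_tree.nwk", "w") as fh:
                fh.write(tree.as_newick() + "\n")
            io.write_groups_tsv(ortho, outdir / "ortholog_groups.tsv")
            summary["stages"]["orthologs"] = {
                "n_groups": len(ortho),
                "groups": {
                    str(g.group_id): sorted(g.members) for g in ortho
                },
            }
        else:
            raise ValueError(
                "tree stage requires >= 3 intact sequences of equal length "
                "(supply pre-aligned sequences)"
            )

    # -- pseudogene calling -------------------------------------------------
    reports = [
        call_disruptions(
            s,
            references[s.locus],
            semiglobal=config.semiglobal or s.source == "resequenced",
            min_identity=config.min_identity,
        )
        for s in sequences
    ]
    io.write_reports_tsv(reports, outdir / "disruption_reports.tsv")
    io.write_events_tsv(reports, outdir / "disruption_events.tsv")
    classifications = {
        (r.species, r.locus): r.status for r in reports
    }
    if truth_labels is not None:
        for key, st in truth_labels.status.items():
            if st == "absent":
                classifications.setdefault(key, "absent")
    summary["stages"]["call"] = {
        "n_reports": len(reports),
        "n_pseudogene": sum(r.is_pseudogene for r in reports),
        "n_low_confidence": sum(r.low_confidence for r in reports),
    }

    # -- shared disruptions and ancestral loss ------------------------------
    by_locus: dict[str, dict[str, object]] = {}
    for r in reports:
        by_locus.setdefault(r.locus, {})[r.species] = r
    assignments = []
    for locus in sorted(by_locus):
        locus_reports = by_locus[locus]
        shared = find_shared_disruptions(locus_reports, config.tolerance)
        assignments.append(
            infer_ancestral_loss(
                shared,
                locus_reports,
                species_tree,
                aliases=aliases,
                weak_min_inframe_nt=config.weak_min_inframe_nt,
            )
        )
    io.write_loss_tsv(assignments, outdir / "ancestral_loss.tsv")
    ancestral = {
        a.locus: [
            {"branch": c.branch, "evidence": c.evidence,
             "species": sorted(c.species)}
            for c in a.ancestral_calls
        ]
        for a in assignments
        if a.ancestral_calls
    }
    summary["stages"]["shared"] = {
        "n_loci_with_shared_events": sum(
            1 for a in assignments if a.shared_events
        ),
        "n_ancestral_calls": sum(len(a.ancestral_calls) for a in assignments),
        "ancestral_loss": ancestral,
    }

    # -- stats ---------------------------------------------------------------
    table = contingency_table(
        classifications, groups, group_order=(config.group1, config.group2)
    )
    p = fisher_exact(table)
    frac1, frac2 = table.proportions()
    summary["stages"]["stats"] = {
        "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d,
                  "rows": [config.group1, config.group2],
                  "columns": ["pseudogene", "intact"]},
        "pseudogene_fraction": {config.group1: frac1, config.group2: frac2},
        "fisher_p": p,
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
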