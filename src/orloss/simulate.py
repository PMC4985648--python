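"""Synthetic OR-repertoire simulator with planted, lineage-specific disruptions.

Generates single-exon OR-like coding sequences evolved along a species
tree, with ORF-disrupting mutations (nonsense substitutions,
frameshifting indels, and larger in-frame deletions) planted on chosen
branches.  Events planted on an internal branch are inherited by every
descendant species, emulating ancestral pseudogenization; per-species
random absence emulates loci unrecoverable from low-coverage genome
assemblies.  Ground-truth labels (intact / pseudogene / absent, realized
event coordinates, and the branch each event occurred on) are returned
alongside the sequences so that every downstream stage of the pipeline
can be validated without external data.

The sequence model is deliberately minimal: ancestral CDSs are random
sense codons between a fixed ATG and TAA, substitutions are uniform
(Jukes-Cantor-like) with rejection of changes that would create an
unplanted in-frame stop, and no selection, rate variation or codon-usage
structure is modelled.  Structural correctness of downstream inference,
not sequence realism, is the target.

To keep truth labels exactly derivable from the plan, the start codon,
the terminal stop and all planted-lesion codons of a locus are protected
from random substitution.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .pseudogenes import (
    ReferenceProfile,
    left_normalize_deletion,
    left_normalize_insertion,
)
from .sequences import NUCLEOTIDES, ORSequence, SENSE_CODONS, STOP_CODONS
from .shared import SpeciesTree

NONSENSE = "nonsense"
INSERTION = "insertion"
DELETION = "deletion"

INTACT = "intact"
PSEUDOGENE = "pseudogene"
ABSENT = "absent"


@dataclass(frozen=True)
class PlannedDisruption:
    """One mutation to plant on a species-tree branch.

    ``branch`` names the edge by its child node (an internal-node label
    for ancestral events, a species name for terminal ones).
    ``codon_position`` is the 1-based codon index on the ancestral CDS;
    positions 1 (start) and the terminal stop are off limits.
    """

    locus: str
    branch: str
    event: str  # "nonsense" | "deletion" | "insertion"
    codon_position: int
    length_nt: int = 0

    def __post_init__(self) -> None:
        if self.event not in (NONSENSE, DELETION, INSERTION):
            raise ValueError(f"unknown event type {self.event!r}")
        if self.event in (DELETION, INSERTION) and self.length_nt < 1:
            raise ValueError("indel events require length_nt >= 1")
        if self.event == NONSENSE and self.length_nt != 0:
            raise ValueError("nonsense events have length_nt == 0")


@dataclass(frozen=True)
class RealizedDisruption:
    """A planted event with its realized (left-normalized) reference coordinate."""

    locus: str
    branch: str
    kind: str
    ref_codon: int
    length_nt: int

    @property
    def signature(self) -> tuple[str, int, int]:
        return (self.kind, self.ref_codon, self.length_nt)

    @property
    def disrupting(self) -> bool:
        return self.kind == NONSENSE or self.length_nt % 3 != 0


@dataclass
class TruthLabels:
    """Ground truth for one simulated repertoire."""

    status: dict[tuple[str, str], str]
    events: dict[tuple[str, str], tuple[tuple[str, int, int], ...]]
    planted: tuple[RealizedDisruption, ...]

    def loci_with_ancestral_loss(self, branch: str) -> set[str]:
        """Loci carrying at least one disrupting event planted on ``branch``."""
        return {
            p.locus for p in self.planted if p.branch == branch and p.disrupting
        }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic repertoire.

    ``substitution_rate`` is the expected number of substitutions per
    site per unit branch length; ``absence_prob`` is either one
    probability for all species or a per-species mapping of the chance
    that a locus is unrecoverable from that species' assembly.
    """

    species_tree: SpeciesTree
    n_loci: int
    codon_length: int = 310
    substitution_rate: float = 0.0
    disruption_plan: tuple[PlannedDisruption, ...] = ()
    absence_prob: float | dict[str, float] = 0.0
    seed: int = 0
    locus_prefix: str = "OR"

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        # aa length is codon_length - 1 (ATG counted, stop not); the intact
        # filter requires strictly more than 250 aa
        if self.codon_length <= 251:
            raise ValueError(
                "codon_length must exceed 251 so undisrupted genes pass the "
                ">250-aa intact filter"
            )
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        for sp, p in self._absence_items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"absence_prob for {sp!r} outside [0, 1]")
        if len(self.species_tree.species) < 2:
            raise ValueError("species tree needs >= 2 leaves")
        valid_branches = self.species_tree.branch_names() - {
            self.species_tree.tree.seed_node.branch_name
        }
        loci = set(self.locus_names())
        for pd in self.disruption_plan:
            if pd.branch not in valid_branches:
                raise ValueError(f"unknown branch {pd.branch!r} in disruption plan")
            if pd.locus not in loci:
                raise ValueError(f"planned disruption on unknown locus {pd.locus!r}")
            if not 2 <= pd.codon_position <= self.codon_length - 1:
                raise ValueError(
                    f"codon_position {pd.codon_position} outside [2, {self.codon_length - 1}]"
                )

    def _absence_items(self):
        if isinstance(self.absence_prob, dict):
            return sorted(self.absence_prob.items())
        return [(sp, self.absence_prob) for sp in sorted(self.species_tree.species)]

    def absence_for(self, species: str) -> float:
        if isinstance(self.absence_prob, dict):
            return self.absence_prob.get(species, 0.0)
        return self.absence_prob

    def locus_names(self) -> list[str]:
        width = max(2, len(str(self.n_loci)))
        return [f"{self.locus_prefix}{i:0{width}d}" for i in range(1, self.n_loci + 1)]


@dataclass
class SimulationResult:
    sequences: list[ORSequence]
    references: dict[str, ReferenceProfile]
    gene_trees: dict[str, str]  # locus -> newick of the pruned true tree
    labels: TruthLabels
    config: SimulationConfig


def default_tm_intervals(codon_length: int, n_helices: int = 7, helix_len: int = 21
                         ) -> tuple[tuple[int, int], ...]:
    """Evenly spaced synthetic transmembrane helix intervals (1-based codons)."""
    lo, hi = 20, codon_length - 15
    span = hi - lo - helix_len
    starts = [lo + round(i * span / (n_helices - 1)) for i in range(n_helices)]
    return tuple((s, s + helix_len - 1) for s in starts)


def _random_cds(rng: np.random.Generator, codon_length: int) -> str:
    body = rng.choice(len(SENSE_CODONS), size=codon_length - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


class _Lineage:
    """Mutable per-lineage alignment-view state.

    ``ref_idx[i]`` is the ancestral-CDS coordinate of column i (None for
    inserted columns); ``base[i]`` is the current base (None if deleted).
    """

    __slots__ = ("ref_idx", "base", "events")

    def __init__(self, ref_idx, base, events):
        self.ref_idx = ref_idx
        self.base = base
        self.events = events

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.ref_idx), list(self.base), list(self.events))

    def emit(self) -> str:
        return "".join(b for b in self.base if b is not None)


def _apply_substitutions(
    lin: _Lineage,
    rng: np.random.Generator,
    p: float,
    protected: set[int],
) -> None:
    if p <= 0:
        return
    # map columns to emitted positions so stop-creation is checked in the
    # lineage's own (current) reading frame
    emitted_cols = [i for i, b in enumerate(lin.base) if b is not None]
    hits = np.nonzero(rng.random(len(emitted_cols)) < p)[0]
    for h in hits:
        col = emitted_cols[h]
        if lin.ref_idx[col] is None or lin.ref_idx[col] in protected:
            continue
        codon_start = (h // 3) * 3
        codon_cols = emitted_cols[codon_start : codon_start + 3]
        if len(codon_cols) < 3:
            continue  # trailing partial codon after a frameshift
        old = lin.base[col]
        within = codon_cols.index(col)
        codon = [lin.base[c] for c in codon_cols]
        choices = []
        for b in NUCLEOTIDES:
            if b == old:
                continue
            trial = codon.copy()
            trial[within] = b
            if "".join(trial) not in STOP_CODONS:
                choices.append(b)
        if not choices:
            continue
        lin.base[col] = choices[int(rng.integers(len(choices)))]


def _apply_planted(
    lin: _Lineage,
    pd: PlannedDisruption,
    ref_cds: str,
    rng: np.random.Generator,
) -> RealizedDisruption:
    nt0 = 3 * (pd.codon_position - 1)
    if pd.event == NONSENSE:
        cols = [i for i, r in enumerate(lin.ref_idx) if r is not None and nt0 <= r < nt0 + 3]
        if len(cols) != 3 or any(lin.base[c] is None for c in cols):
            raise ValueError(
                f"cannot plant nonsense at codon {pd.codon_position} of {pd.locus}: "
                "site altered by an earlier planted event"
            )
        for c, b in zip(cols, "TAA"):
            lin.base[c] = b
        realized = RealizedDisruption(pd.locus, pd.branch, NONSENSE, pd.codon_position, 0)
    elif pd.event == DELETION:
        cols = [
            i
            for i, r in enumerate(lin.ref_idx)
            if r is not None and nt0 <= r < nt0 + pd.length_nt and lin.base[i] is not None
        ]
        if len(cols) != pd.length_nt:
            raise ValueError(
                f"cannot plant deletion at codon {pd.codon_position} of {pd.locus}: "
                "overlaps an earlier planted event"
            )
        for c in cols:
            lin.base[c] = None
        start = left_normalize_deletion(ref_cds, nt0, pd.length_nt)
        realized = RealizedDisruption(
            pd.locus, pd.branch, DELETION, start // 3 + 1, pd.length_nt
        )
    else:  # insertion
        if pd.length_nt % 3 == 0:
            ncod = pd.length_nt // 3
            seg = "".join(
                SENSE_CODONS[int(i)] for i in rng.choice(len(SENSE_CODONS), size=ncod)
            )
        else:
            seg = "".join(
                NUCLEOTIDES[int(i)] for i in rng.integers(0, 4, size=pd.length_nt)
            )
        at = next(
            (i for i, r in enumerate(lin.ref_idx) if r is not None and r >= nt0),
            len(lin.ref_idx),
        )
        lin.ref_idx[at:at] = [None] * pd.length_nt
        lin.base[at:at] = list(seg)
        pos, _ = left_normalize_insertion(ref_cds, seg, nt0)
        realized = RealizedDisruption(
            pd.locus, pd.branch, INSERTION, pos // 3 + 1, pd.length_nt
        )
    lin.events.append(realized)
    return realized


def simulate_repertoire(config: SimulationConfig) -> SimulationResult:
    """Evolve ``n_loci`` OR-like genes along the species tree.

    Deterministic for a given config and seed.  Returns the emitted
    (non-absent) sequences, per-locus reference profiles (the ancestral
    CDS with synthetic TM intervals), per-locus true trees pruned to the
    non-absent species, and :class:`TruthLabels`.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.species_tree
    loci = config.locus_names()
    plan_by_locus: dict[str, list[PlannedDisruption]] = {}
    for pd in config.disruption_plan:
        plan_by_locus.setdefault(pd.locus, []).append(pd)

    sequences: list[ORSequence] = []
    references: dict[str, ReferenceProfile] = {}
    gene_trees: dict[str, str] = {}
    status: dict[tuple[str, str], str] = {}
    events: dict[tuple[str, str], tuple[tuple[str, int, int], ...]] = {}
    planted_realized: dict[tuple[str, str, str, int, int], RealizedDisruption] = {}

    tm = default_tm_intervals(config.codon_length)

    for locus in loci:
        ref_cds = _random_cds(rng, config.codon_length)
        references[locus] = ReferenceProfile(locus=locus, cds=ref_cds, tm_intervals=tm)
        plan = plan_by_locus.get(locus, [])
        protected: set[int] = {0, 1, 2}
        protected |= set(range(len(ref_cds) - 3, len(ref_cds)))
        for pd in plan:
            nt0 = 3 * (pd.codon_position - 1)
            span = 3 if pd.event == NONSENSE else max(pd.length_nt, 3)
            protected |= set(range(nt0, nt0 + span))

        root_lin = _Lineage(list(range(len(ref_cds))), list(ref_cds), [])
        leaf_states: dict[str, _Lineage] = {}

        def evolve(node, lin: _Lineage) -> None:
            if node.parent_node is not None:
                lin = lin.copy()
                elen = node.edge.length if node.edge.length is not None else 1.0
                p = min(1.0, config.substitution_rate * elen)
                _apply_substitutions(lin, rng, p, protected)
                for pd in plan:
                    if pd.branch == node.branch_name:
                        realized = _apply_planted(lin, pd, ref_cds, rng)
                        planted_realized[
                            (locus, pd.branch, pd.event, pd.codon_position, pd.length_nt)
                        ] = realized
            if node.is_leaf():
                leaf_states[node.taxon.label] = lin
            else:
                for child in node.child_nodes():
                    evolve(child, lin)

        evolve(tree.tree.seed_node, root_lin)

        present: list[str] = []
        for species in sorted(tree.species):
            lin = leaf_states[species]
            absent = rng.random() < config.absence_for(species)
            if absent:
                status[(species, locus)] = ABSENT
                events[(species, locus)] = ()
                continue
            present.append(species)
            sig = tuple(e.signature for e in lin.events)
            events[(species, locus)] = sig
            is_pseudo = any(e.disrupting for e in lin.events)
            status[(species, locus)] = PSEUDOGENE if is_pseudo else INTACT
            sequences.append(
                ORSequence(
                    id=f"{species}|{locus}",
                    species=species,
                    locus=locus,
                    seq=lin.emit(),
                    source="synthetic",
                )
            )

        if len(present) >= 2:
            sub = tree.tree.extract_tree_with_taxa_labels(present)
            gene_trees[locus] = sub.as_string(schema="newick", suppress_rooting=True).strip()
        else:
            gene_trees[locus] = ";".join(present) + ";" if present else ";"

    labels = TruthLabels(
        status=status,
        events=events,
        planted=tuple(planted_realized.values()),
    )
    return SimulationResult(
        sequences=sequences,
        references=references,
        gene_trees=gene_trees,
        labels=labels,
        config=config,
    )


# ---------------------------------------------------------------------------
# default study conditions: the eight-waterbird scenario


WATERBIRD_NEWICK = (
    "((((emperor_penguin:0.5,adelie_penguin:0.5)penguins:0.25,"
    "northern_fulmar:0.75)sphenisciformes_procellariiformes:0.25,"
    "((crested_ibis:0.5,little_egret:0.5)ibis_egret:0.25,"
    "(great_cormorant:0.5,dalmatian_pelican:0.5)cormorant_pelican:0.25)"
    "pelecaniformes:0.25)core_waterbirds:0.25,red_throated_loon:1.25)root;"
)

PENGUIN_SPECIES = ("emperor_penguin", "adelie_penguin")
PENGUIN_STEM = "penguins"

#: per-species locus-absence probabilities, decreasing with assembly coverage
#: (the 105x ibis loses almost nothing; the 24x cormorant loses the most)
WATERBIRD_ABSENCE = {
    "emperor_penguin": 0.15,
    "adelie_penguin": 0.15,
    "northern_fulmar": 0.30,
    "crested_ibis": 0.035,
    "little_egret": 0.24,
    "great_cormorant": 0.41,
    "dalmatian_pelican": 0.21,
    "red_throated_loon": 0.28,
}


def waterbird_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(WATERBIRD_NEWICK)


def waterbird_disruption_plan() -> tuple[PlannedDisruption, ...]:
    """Eight penguin-stem pseudogenization events plus three private ones.

    Mirrors the canonical shared-lesion layout: a compensating 2-bp
    deletion/2-bp insertion pair, single shared nonsense substitutions, a
    10-bp deletion with upstream shared stops, a 2-bp deletion, a 1-bp
    insertion, and one locus whose penguins share only a large (12-bp)
    in-frame deletion while each carries a private nonsense mutation
    (weak-evidence ancestral case).  Three further events are private to
    single non-penguin species.
    """
    P = PENGUIN_STEM
    return (
        PlannedDisruption("OR03", P, DELETION, 40, 2),
        PlannedDisruption("OR03", P, INSERTION, 70, 2),
        PlannedDisruption("OR04", P, NONSENSE, 50),
        PlannedDisruption("OR07", P, NONSENSE, 120),
        PlannedDisruption("OR07", P, NONSENSE, 140),
        PlannedDisruption("OR07", P, DELETION, 200, 10),
        PlannedDisruption("OR09", P, DELETION, 57, 2),
        PlannedDisruption("OR13", P, NONSENSE, 30),
        PlannedDisruption("OR19", P, DELETION, 150, 12),
        PlannedDisruption("OR19", "emperor_penguin", NONSENSE, 40),
        PlannedDisruption("OR19", "adelie_penguin", NONSENSE, 90),
        PlannedDisruption("OR22", P, NONSENSE, 45),
        PlannedDisruption("OR25", P, INSERTION, 100, 1),
        PlannedDisruption("OR10", "northern_fulmar", NONSENSE, 35),
        PlannedDisruption("OR16", "northern_fulmar", DELETION, 80, 1),
        PlannedDisruption("OR25", "red_throated_loon", NONSENSE, 55),
    )


def waterbird_scenario(
    seed: int = 0,
    n_loci: int = 29,
    codon_length: int = 310,
    substitution_rate: float = 0.02,
    with_absence: bool = True,
) -> SimulationConfig:
    """The default study conditions: 8 waterbird species, 29 loci,
    penguin-stem disruptions on 8 loci and coverage-dependent absence.

    With fewer loci (scaled-down runs) plan entries for missing loci are
    dropped; planted codon positions are kept within range for any
    ``codon_length`` the config accepts.
    """
    tree = waterbird_species_tree()
    probe = SimulationConfig(
        species_tree=tree, n_loci=n_loci, codon_length=codon_length
    )
    loci = set(probe.locus_names())
    plan = tuple(
        pd
        for pd in waterbird_disruption_plan()
        if pd.locus in loci and pd.codon_position <= codon_length - 1
    )
    return SimulationConfig(
        species_tree=tree,
        n_loci=n_loci,
        codon_length=codon_length,
        substitution_rate=substitution_rate,
        disruption_plan=plan,
        absence_prob=WATERBIRD_ABSENCE if with_absence else 0.0,
        seed=seed,
    )
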