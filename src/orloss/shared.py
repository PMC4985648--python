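"""Shared disruptions across species and Dollo-style ancestral-loss inference.

The same ORF-disrupting mutation found at the homologous reference
position in several species is most parsimoniously explained by a single
event in their common ancestor.  Each shared disruption signature is
therefore assigned to the stem branch of the most recent common ancestor
(MRCA) of its carriers on the species tree; species-private disruptions
sit on terminal branches.  A locus is called ancestrally pseudogenized
for a clade when at least one shared *disrupting* signature (nonsense or
frameshifting indel) maps onto the clade's stem branch.

A separate weak-evidence rule covers loci where the species of a clade
are all pseudogenized and share a large in-frame deletion (default
>= 12 nt) while their frame-disrupting mutations are private: the
shared deletion plus independent disruptions suggest relaxed constraint
before the split, but the strict single-event logic does not apply, so
such calls are reported apart and never pooled with strict calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .pseudogenes import DisruptionReport

STRICT = "strict"
WEAK = "weak"


class SpeciesTree:
    """A rooted species phylogeny; branches are named by their child node.

    Unnamed internal nodes receive stable auto-labels (``node_<k>`` in
    preorder) so every branch is addressable.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        tree.is_rooted = True
        self.tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) != len(set(leaves)):
            raise ValueError("duplicate species names in species tree")
        self.species = frozenset(leaves)
        k = 0
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                nd.branch_name = nd.taxon.label
            else:
                if nd.label is None:
                    k += 1
                    nd.label = f"node_{k}"
                nd.branch_name = nd.label

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        return cls(dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True))

    def branch_names(self) -> set[str]:
        return {nd.branch_name for nd in self.tree.preorder_node_iter()}

    def mrca_branch(self, species: set[str]) -> str:
        missing = set(species) - self.species
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        if len(species) == 1:
            return next(iter(species))
        node = self.tree.mrca(taxon_labels=sorted(species))
        return node.branch_name

    def leaves_under_branch(self, branch: str) -> frozenset[str]:
        for nd in self.tree.preorder_node_iter():
            if nd.branch_name == branch:
                return frozenset(lf.taxon.label for lf in nd.leaf_iter())
        raise ValueError(f"unknown branch {branch!r}")

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class SharedEvent:
    """One disruption signature carried by >= 2 species at homologous positions."""

    locus: str
    kind: str
    ref_codon: int
    length_nt: int
    species: frozenset[str]
    branch: str | None = None
    #: per-carrier (species, ref_codon) pairs before tolerance clustering
    members: tuple[tuple[str, int], ...] = ()

    @property
    def disrupting(self) -> bool:
        return self.kind == "nonsense" or self.length_nt % 3 != 0

    @property
    def signature(self) -> tuple[str, int, int]:
        return (self.kind, self.ref_codon, self.length_nt)


@dataclass(frozen=True)
class AncestralLossCall:
    locus: str
    branch: str
    species: frozenset[str]
    evidence: str  # "strict" | "weak"
    signatures: tuple[tuple[str, int, int], ...]


@dataclass(frozen=True)
class TerminalEvent:
    locus: str
    species: str
    signature: tuple[str, int, int]


@dataclass(frozen=True)
class LossAssignment:
    locus: str
    ancestral_calls: tuple[AncestralLossCall, ...]
    terminal_events: tuple[TerminalEvent, ...]
    shared_events: tuple[SharedEvent, ...]


def find_shared_disruptions(
    reports: dict[str, DisruptionReport],
    tolerance_codons: int = 0,
) -> list[SharedEvent]:
    """Group homologous disruptions across species for one locus.

    Two disruptions match when they have the same kind, the same length
    (for indels) and reference codons within ``tolerance_codons`` of each
    other (default 0 = exact coordinate, as expected after left
    normalization against a common reference).  Maximal species sets are
    reported per signature; frame-induced secondary stops are excluded
    from matching (the causal frameshift itself is matched instead).
    """
    loci = {r.locus for r in reports.values()}
    if len(loci) > 1:
        raise ValueError(f"reports mix loci: {sorted(loci)}")
    if not reports:
        return []
    locus = loci.pop()

    # (kind, length) -> list of (ref_codon, species)
    by_type: dict[tuple[str, int], list[tuple[int, str]]] = {}
    for species in sorted(reports):
        for d in reports[species].primary_events():
            by_type.setdefault((d.kind, d.length_nt), []).append((d.ref_codon, species))

    events: list[SharedEvent] = []
    for (kind, length), hits in sorted(by_type.items()):
        hits.sort()
        # cluster codons whose neighbours are within tolerance
        cluster: list[tuple[int, str]] = []
        clusters: list[list[tuple[int, str]]] = []
        for codon, sp in hits:
            if cluster and codon - cluster[-1][0] > tolerance_codons:
                clusters.append(cluster)
                cluster = []
            cluster.append((codon, sp))
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            carriers = frozenset(sp for _, sp in cl)
            if len(carriers) < 2:
                continue
            events.append(
                SharedEvent(
                    locus=locus,
                    kind=kind,
                    ref_codon=min(c for c, _ in cl),
                    length_nt=length,
                    species=carriers,
                    members=tuple((sp, c) for c, sp in cl),
                )
            )
    events.sort(key=lambda e: (e.ref_codon, e.kind, e.length_nt))
    return events


def infer_ancestral_loss(
    shared: list[SharedEvent],
    reports: dict[str, DisruptionReport],
    tree: SpeciesTree,
    aliases: dict[str, str] | None = None,
    weak_min_inframe_nt: int = 12,
) -> LossAssignment:
    """Assign disruption events of one locus to species-tree branches.

    Dollo-style single-origin rule: every shared signature is placed on
    the stem branch of the MRCA of its carriers; private disrupting
    events go to terminal branches.  ``aliases`` maps sequenced species
    to the tree species they stand in for (congener substitution, e.g.
    king penguin sequenced in place of the emperor penguin).

    Weak-evidence calls (all clade species pseudogenized and sharing an
    in-frame deletion >= ``weak_min_inframe_nt``) are reported with
    ``evidence == "weak"`` and must not be pooled with strict calls.
    """
    aliases = aliases or {}
    loci = {r.locus for r in reports.values()} | {e.locus for e in shared}
    if len(loci) > 1:
        raise ValueError(f"inputs mix loci: {sorted(loci)}")
    locus = loci.pop() if loci else ""

    def to_tree_species(sp: str) -> str:
        return aliases.get(sp, sp)

    resolved: list[SharedEvent] = []
    for ev in shared:
        carriers = frozenset(to_tree_species(s) for s in ev.species)
        branch = tree.mrca_branch(set(carriers))
        resolved.append(
            SharedEvent(
                locus=ev.locus,
                kind=ev.kind,
                ref_codon=ev.ref_codon,
                length_nt=ev.length_nt,
                species=carriers,
                branch=branch,
                members=tuple((to_tree_species(s), c) for s, c in ev.members),
            )
        )

    # strict ancestral calls: shared *disrupting* signatures, grouped by branch
    by_branch: dict[str, list[SharedEvent]] = {}
    for ev in resolved:
        if ev.disrupting:
            by_branch.setdefault(ev.branch, []).append(ev)
    calls = [
        AncestralLossCall(
            locus=locus,
            branch=branch,
            species=frozenset().union(*(e.species for e in evs)),
            evidence=STRICT,
            signatures=tuple(sorted(e.signature for e in evs)),
        )
        for branch, evs in sorted(by_branch.items())
    ]

    # weak rule: shared large in-frame deletion in an all-pseudogene clade
    strict_branches = {c.branch for c in calls}
    for ev in resolved:
        if ev.disrupting or ev.kind != "deletion" or ev.length_nt < weak_min_inframe_nt:
            continue
        if ev.branch in strict_branches:
            continue
        carriers_seq = {s for s in reports if to_tree_species(s) in ev.species}
        if carriers_seq and all(reports[s].is_pseudogene for s in carriers_seq):
            calls.append(
                AncestralLossCall(
                    locus=locus,
                    branch=ev.branch,
                    species=ev.species,
                    evidence=WEAK,
                    signatures=(ev.signature,),
                )
            )

    # private disrupting events on terminal branches
    shared_sigs = {
        ((ev.kind, codon, ev.length_nt), sp)
        for ev in resolved
        for sp, codon in (ev.members or tuple((s, ev.ref_codon) for s in ev.species))
    }
    terminals: list[TerminalEvent] = []
    for sp in sorted(reports):
        tree_sp = to_tree_species(sp)
        if tree_sp not in tree.species:
            raise ValueError(f"species {tree_sp!r} not in species tree")
        for d in reports[sp].primary_events():
            if not d.disrupting:
                continue
            if (d.signature, tree_sp) in shared_sigs:
                continue
            terminals.append(TerminalEvent(locus=locus, species=tree_sp, signature=d.signature))

    return LossAssignment(
        locus=locus,
        ancestral_calls=tuple(calls),
        terminal_events=tuple(terminals),
        shared_events=tuple(resolved),
    )
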