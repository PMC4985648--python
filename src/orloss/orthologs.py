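"""One-to-one ortholog group extraction from support-annotated gene trees.

A putative one-to-one ortholog group is a clade of a gene tree that (i)
is well supported (bootstrap strictly greater than a threshold, default
85%), (ii) contains at most one gene per species, and (iii) spans at
least a minimum number of species (default 4).  Only maximal qualifying
clades are returned — a qualifying clade nested inside another
qualifying clade is absorbed by it — and groups are numbered by preorder
appearance on the tree, mirroring the numeric gene naming convention.

A neighbor-joining tree builder with site-resampling bootstrap is
provided as plumbing for self-contained synthetic runs; it does not
attempt to reproduce ML/Bayesian inference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj


@dataclass(frozen=True)
class OrthologCriteria:
    """Thresholds for one-to-one ortholog clades.

    ``min_support_exclusive`` is strict: support must be *greater than*
    this value (default 85, on a 0-100 scale).  Posterior probabilities
    supplied on a 0-1 scale are rescaled to 0-100 at parse time.
    """

    min_support_exclusive: float = 85.0
    max_copies_per_species: int = 1
    min_species: int = 4

    def __post_init__(self) -> None:
        if self.min_species < 2:
            raise ValueError("min_species must be >= 2")


@dataclass(frozen=True)
class OrthologGroup:
    """A single-copy, well-supported, multi-species clade treated as one locus."""

    group_id: int
    members: dict[str, str]  # species -> gene id
    support: float
    node_leaves: frozenset[str]

    @property
    def n_species(self) -> int:
        return len(self.members)


class GeneTree:
    """A rooted gene tree with clade supports and per-leaf (species, gene) metadata.

    Internal node labels are interpreted as the support of the clade
    below them (common newick convention).  Leaf names of the form
    ``species|gene`` are parsed automatically; otherwise an explicit
    ``leaf_meta`` map must be supplied.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        leaf_meta: dict[str, tuple[str, str]] | None = None,
        outgroup: str | None = None,
    ) -> None:
        self.tree = tree
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf names in gene tree")
        if leaf_meta is None:
            leaf_meta = {}
            for name in names:
                parts = name.split("|")
                if len(parts) >= 2:
                    leaf_meta[name] = (parts[0], parts[-1])
                else:
                    leaf_meta[name] = (name, name)
        missing = set(names) - set(leaf_meta) - ({outgroup} if outgroup else set())
        if missing:
            raise ValueError(f"no metadata for leaves: {sorted(missing)}")
        self.leaf_meta = leaf_meta
        self.outgroup = outgroup
        self._supports_scaled = False
        self._scale_supports()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        leaf_meta: dict[str, tuple[str, str]] | None = None,
        outgroup: str | None = None,
    ) -> "GeneTree":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(tree, leaf_meta=leaf_meta, outgroup=outgroup)

    def _scale_supports(self) -> None:
        """Rescale 0-1 posterior supports to the 0-100 bootstrap scale."""
        vals = []
        for nd in self.tree.preorder_internal_node_iter():
            if nd.label is not None:
                try:
                    vals.append(float(nd.label))
                except ValueError:
                    pass
        if vals and max(vals) <= 1.0:
            for nd in self.tree.preorder_internal_node_iter():
                try:
                    nd.label = str(float(nd.label) * 100.0) if nd.label is not None else None
                except ValueError:
                    pass
        self._supports_scaled = True

    # -- rooting -----------------------------------------------------------

    def root(self) -> None:
        """Root on the outgroup leaf if set, else at the midpoint."""
        if self.outgroup is not None:
            og = self.tree.find_node_with_taxon_label(self.outgroup)
            if og is None:
                raise ValueError(f"outgroup leaf {self.outgroup!r} not in tree")
            self.tree.reroot_at_edge(og.edge, update_bipartitions=False)
        else:
            if any(
                nd.edge.length is None
                for nd in self.tree.preorder_node_iter()
                if nd.parent_node is not None
            ):
                raise ValueError(
                    "cannot midpoint-root a tree without branch lengths; "
                    "supply an outgroup"
                )
            self.tree.reroot_at_midpoint(update_bipartitions=False)

    # -- queries -----------------------------------------------------------

    def support_of(self, node: dendropy.Node) -> float | None:
        if node.label is None:
            return None
        try:
            return float(node.label)
        except ValueError:
            return None

    def clade_leaves(self, node: dendropy.Node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _qualifies(
    tree: GeneTree, node: dendropy.Node, criteria: OrthologCriteria
) -> dict[str, str] | None:
    if node.is_leaf() or node.parent_node is None:
        return None
    support = tree.support_of(node)
    if support is None or not support > criteria.min_support_exclusive:
        return None
    leaves = [n for n in tree.clade_leaves(node) if n != tree.outgroup]
    species = Counter(tree.leaf_meta[n][0] for n in leaves)
    if any(c > criteria.max_copies_per_species for c in species.values()):
        return None
    if len(species) < criteria.min_species:
        return None
    return {tree.leaf_meta[n][0]: tree.leaf_meta[n][1] for n in leaves}


def extract_ortholog_clades(
    tree: GeneTree, criteria: OrthologCriteria = OrthologCriteria()
) -> list[OrthologGroup]:
    """Return maximal qualifying one-to-one ortholog clades, in preorder.

    The tree must be rooted (call :meth:`GeneTree.root` first when an
    outgroup or branch lengths are available).  When a qualifying clade
    is found its subtree is not descended further, so returned groups
    are node-disjoint.
    """
    groups: list[OrthologGroup] = []

    def visit(node: dendropy.Node) -> None:
        members = _qualifies(tree, node, criteria)
        if members is not None:
            groups.append(
                OrthologGroup(
                    group_id=len(groups) + 1,
                    members=members,
                    support=tree.support_of(node) or 0.0,
                    node_leaves=frozenset(
                        n for n in tree.clade_leaves(node) if n != tree.outgroup
                    ),
                )
            )
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.tree.seed_node)
    return groups


# ---------------------------------------------------------------------------
# neighbor-joining plumbing for synthetic end-to-end runs


_ENC = np.full(256, -1, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _ENC[ord(base)] = i


def _encode_alignment(seqs: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _ENC[arr].reshape(len(seqs), -1)


def _p_distance_matrix(enc: np.ndarray) -> np.ndarray:
    """Pairwise p-distance with pairwise deletion of gap/N sites.

    Pairs with no comparable sites get the saturation value 0.75.
    """
    n = enc.shape[0]
    dm = np.zeros((n, n))
    valid = enc >= 0
    for i in range(n):
        both = valid[i] & valid
        comparable = both.sum(axis=1)
        mism = ((enc[i] != enc) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(comparable > 0, mism / np.maximum(comparable, 1), 0.75)
        dm[i] = d
    np.fill_diagonal(dm, 0.0)
    return np.maximum(dm, dm.T)


def _nj_newick(dm: np.ndarray, names: list[str]) -> str:
    sk_dm = DistanceMatrix(dm, ids=names)
    return str(_skbio_nj(sk_dm))


def _splits(tree: dendropy.Tree, taxa: frozenset[str], ref: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalized as the side not containing ``ref``."""
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


def build_gene_tree(
    seqs: dict[str, str] | list[tuple[str, str]],
    n_bootstrap: int = 100,
    seed: int = 0,
) -> GeneTree:
    """Neighbor-joining tree with site-resampling bootstrap supports.

    ``seqs`` maps leaf name to an aligned nucleotide sequence (equal
    lengths; gaps ``-`` and ``N`` are pairwise-deleted when computing
    p-distances).  Supports are percentages of ``n_bootstrap``
    column-resampled replicates containing each internal bipartition;
    with ``n_bootstrap == 0`` supports are absent.  Deterministic for a
    given seed.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    names = [n for n, _ in items]
    rows = [s.upper() for _, s in items]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names")
    if len(names) < 3:
        raise ValueError("need at least 3 sequences")
    width = {len(s) for s in rows}
    if len(width) != 1:
        raise ValueError("sequences must be aligned to equal length")
    if width == {0}:
        raise ValueError("alignment width is zero")

    enc = _encode_alignment(rows)
    main = dendropy.Tree.get(data=_nj_newick(_p_distance_matrix(enc), names), schema="newick", preserve_underscores=True)

    if n_bootstrap > 0:
        taxa = frozenset(names)
        ref = names[0]
        rng = np.random.default_rng(seed)
        counts: dict[frozenset[str], int] = {}
        ncols = enc.shape[1]
        for _ in range(n_bootstrap):
            cols = rng.integers(0, ncols, size=ncols)
            rep = dendropy.Tree.get(
                data=_nj_newick(_p_distance_matrix(enc[:, cols]), names),
                schema="newick", preserve_underscores=True,
            )
            for split in _splits(rep, taxa, ref):
                counts[split] = counts.get(split, 0) + 1
        for node in main.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = taxa - side
            if 2 <= len(side) <= len(taxa) - 2:
                node.label = str(round(100.0 * counts.get(side, 0) / n_bootstrap, 1))

    return GeneTree(main)
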