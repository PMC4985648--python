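"""Ortholog-clade extraction criteria, maximality, and the NJ plumbing."""

import itertools

import dendropy
import numpy as np
import pytest

from orloss import (
    GeneTree,
    OrthologCriteria,
    build_gene_tree,
    extract_ortholog_clades,
)


# -- random tree generation and the brute-force oracle ------------------------


def random_gene_tree(rng: np.random.Generator, n_leaves: int) -> GeneTree:
    """Random rooted binary tree with random species labels and supports."""
    species_pool = [f"sp{i}" for i in range(8)]
    leaves = [
        f"{rng.choice(species_pool)}|g{i}" for i in range(n_leaves)
    ]
    nodes = [f"{name}" for name in leaves]
    newicks = list(nodes)
    k = 0
    while len(newicks) > 1:
        i, j = sorted(rng.choice(len(newicks), size=2, replace=False))
        b = newicks.pop(j)
        a = newicks.pop(i)
        support = int(rng.integers(0, 101))
        k += 1
        newicks.append(f"({a}:1,{b}:1){support}:1")
    return GeneTree.from_newick(newicks[0] + ";")


def oracle_groups(tree: GeneTree, criteria: OrthologCriteria):
    """Independent enumeration: test every internal node, keep nodes with no
    qualifying proper ancestor."""
    qualifying = []
    for node in tree.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        label = node.label
        try:
            support = float(label) if label is not None else None
        except ValueError:
            support = None
        if support is None or support <= criteria.min_support_exclusive:
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label != tree.outgroup]
        species = [tree.leaf_meta[n][0] for n in leaves]
        if len(set(species)) < criteria.min_species:
            continue
        if any(species.count(s) > criteria.max_copies_per_species for s in species):
            continue
        qualifying.append(node)
    maximal = []
    for node in qualifying:
        anc = node.parent_node
        has_q_anc = False
        while anc is not None:
            if anc in qualifying:
                has_q_anc = True
                break
            anc = anc.parent_node
        if not has_q_anc:
            maximal.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return set(maximal)


def test_star_tree_has_no_groups():
    gt = GeneTree.from_newick("(sp1|a,sp2|b,sp3|c,sp4|d,sp5|e);")
    assert extract_ortholog_clades(gt) == []


def test_single_supported_clade_recovered():
    # the 5-species clade carries support 90; nested well-supported
    # subclades are absorbed by maximality
    inner = "(sp1|a:1,(sp2|b:1,(sp3|c:1,(sp4|d:1,sp5|e:1)99:1)98:1)97:1)90"
    gt = GeneTree.from_newick(f"({inner}:1,(sp6|f:1,(sp7|g:1,sp8|h:1)20:1)30:1);")
    groups = extract_ortholog_clades(gt)
    assert len(groups) == 1
    g = groups[0]
    assert set(g.members) == {"sp1", "sp2", "sp3", "sp4", "sp5"}
    assert g.support == 90.0
    assert g.group_id == 1


def test_support_85_is_excluded_strictly():
    inner = "((sp1|a:1,sp2|b:1)50:1,(sp3|c:1,sp4|d:1)60:1)85"
    gt = GeneTree.from_newick(f"({inner}:1,(sp6|f:1,sp7|g:1)99:1);")
    assert extract_ortholog_clades(gt) == []
    gt = GeneTree.from_newick(f"({inner.replace(')85', ')85.1')}:1,(sp6|f:1,sp7|g:1)99:1);")
    assert len(extract_ortholog_clades(gt)) == 1


def test_duplicate_species_disqualifies_even_at_full_support():
    inner = "(sp1|a:1,(sp2|b:1,(sp3|c:1,(sp4|d:1,(sp5|e:1,sp5|e2:1)100:1)100:1)100:1)100:1)"
    gt = GeneTree.from_newick(f"({inner}100:1,(sp6|f:1,sp7|g:1)99:1);")
    groups = extract_ortholog_clades(gt)
    # the clade containing both sp5 genes is excluded; the nested clean
    # subclades are too small once sp5's pair is the only 4-species option
    assert all("sp5" not in g.members or len(g.members) >= 4 for g in groups)
    assert not any(set(g.node_leaves) >= {"sp5|e", "sp5|e2"} for g in groups)


def test_posterior_scale_rescaled():
    # Bayesian posteriors on a 0-1 scale are read as percentages
    inner = "((sp1|a:1,sp2|b:1)0.5:1,(sp3|c:1,sp4|d:1)0.4:1)0.99"
    gt = GeneTree.from_newick(f"({inner}:1,sp6|f:1);")
    groups = extract_ortholog_clades(gt)
    assert len(groups) == 1 and groups[0].support == 99.0


def test_extraction_matches_bruteforce_oracle_on_random_trees():
    rng = np.random.default_rng(17)
    criteria = OrthologCriteria()
    for _ in range(100):
        gt = random_gene_tree(rng, int(rng.integers(4, 13)))
        got = {g.node_leaves for g in extract_ortholog_clades(gt, criteria)}
        assert got == oracle_groups(gt, criteria)


def test_groups_are_node_disjoint():
    rng = np.random.default_rng(5)
    for _ in range(30):
        gt = random_gene_tree(rng, 12)
        groups = extract_ortholog_clades(gt, OrthologCriteria(min_species=2))
        for g1, g2 in itertools.combinations(groups, 2):
            assert not (g1.node_leaves & g2.node_leaves)


def test_group_numbering_follows_preorder():
    newick = ("(((sp1|a:1,(sp2|b:1,sp3|c:1)99:1)90:1,"
              "(sp4|d:1,(sp5|e:1,sp6|f:1)99:1)95:1)50:1,sp7|g:1);")
    gt = GeneTree.from_newick(newick)
    groups = extract_ortholog_clades(gt, OrthologCriteria(min_species=3))
    assert [g.group_id for g in groups] == [1, 2]
    assert set(groups[0].members) == {"sp1", "sp2", "sp3"}
    assert set(groups[1].members) == {"sp4", "sp5", "sp6"}


# -- NJ tree builder ----------------------------------------------------------


def test_nj_three_taxa_unique_topology():
    gt = build_gene_tree(
        {"A": "ACGTACGTAC", "B": "ACGTACGTAT", "C": "TTTTACGTAC"}, n_bootstrap=0
    )
    leaves = {lf.taxon.label for lf in gt.tree.leaf_node_iter()}
    assert leaves == {"A", "B", "C"}


def _mutate(seq: str, k: int, rng) -> str:
    """k distinct-site substitutions."""
    s = list(seq)
    for i in rng.choice(len(s), size=k, replace=False):
        s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
    return "".join(s)


def test_nj_recovers_true_split_of_four_taxa():
    """Two cherries separated by a long internal edge; the oracle is the
    four-point condition on the additive p-distances."""
    rng = np.random.default_rng(23)
    root = "".join(rng.choice(list("ACGT"), size=600))
    left = _mutate(root, 60, rng)
    right = _mutate(root, 0, rng)
    seqs = {
        "A": _mutate(left, 5, rng),
        "B": _mutate(left, 5, rng),
        "C": _mutate(right, 5, rng),
        "D": _mutate(right, 5, rng),
    }
    gt = build_gene_tree(seqs, n_bootstrap=100, seed=1)

    def pdist(x, y):
        return sum(a != b for a, b in zip(seqs[x], seqs[y])) / len(seqs[x])

    sums = {
        frozenset([frozenset("AB"), frozenset("CD")]): pdist("A", "B") + pdist("C", "D"),
        frozenset([frozenset("AC"), frozenset("BD")]): pdist("A", "C") + pdist("B", "D"),
        frozenset([frozenset("AD"), frozenset("BC")]): pdist("A", "D") + pdist("B", "C"),
    }
    expected = min(sums, key=sums.get)
    assert frozenset("AB") in expected  # sanity of the construction

    splits = set()
    for node in gt.tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) == 2:
            splits.add(side)
            assert float(node.label) > 85.0  # clean split, high support
    assert splits and all(s in {frozenset("AB"), frozenset("CD")} for s in splits)


def test_nj_bootstrap_zero_leaves_supports_absent():
    rng = np.random.default_rng(2)
    seqs = {n: "".join(rng.choice(list("ACGT"), size=90)) for n in "ABCDE"}
    gt = build_gene_tree(seqs, n_bootstrap=0)
    for node in gt.tree.preorder_internal_node_iter():
        if node.parent_node is not None:
            assert node.label is None


def test_nj_deterministic_given_seed():
    rng = np.random.default_rng(4)
    seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), size=120)) for i in range(6)}
    t1 = build_gene_tree(seqs, n_bootstrap=25, seed=9).as_newick()
    t2 = build_gene_tree(seqs, n_bootstrap=25, seed=9).as_newick()
    assert t1 == t2


def test_nj_input_validation():
    with pytest.raises(ValueError, match="duplicate"):
        build_gene_tree([("A", "ACGT"), ("A", "ACGT"), ("B", "ACGT")])
    with pytest.raises(ValueError, match="width"):
        build_gene_tree({"A": "", "B": "", "C": ""})
    with pytest.raises(ValueError, match="equal length"):
        build_gene_tree({"A": "ACGT", "B": "ACG", "C": "ACGT"})
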