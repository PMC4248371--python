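"""Supermatrix construction, distances, neighbor joining, bootstrap."""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
import pytest

from plastcomp.msa import Msa
from plastcomp.phylo import (
    bipartitions,
    bootstrap_support,
    build_supermatrix,
    is_monophyletic,
    jc_distance_matrix,
    nj_tree,
    parse_newick,
    to_newick,
)


def _msa(rows):
    return Msa(names=list(rows), rows=rows)


def test_supermatrix_concatenation_and_gene_map():
    m1 = _msa({"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGTACGTAC"})
    m2 = _msa({"a": "GGGGCCCCCCTTTTTTTTTT", "b": "GGGGCCCCCCTTTTTTTTTT",
               "c": "GGGGCCCCCCTTTTTTTTTT"})
    sm = build_supermatrix({"g1": m1, "g2": m2})
    assert sm.columns == 30
    assert sm.gene_map == {"g1": (0, 10), "g2": (10, 30)}


def test_missing_taxon_gap_padded():
    m1 = _msa({"a": "ACGT", "b": "ACGT"})
    m2 = _msa({"a": "GGCC", "c": "GGCC"})
    sm = build_supermatrix({"g1": m1, "g2": m2})
    assert sm.rows["c"] == "----GGCC"
    assert sm.rows["b"] == "ACGT----"


def test_taxon_in_zero_genes_is_error():
    m1 = _msa({"a": "ACGT", "b": "ACGT"})
    with pytest.raises(ValueError, match="no genes"):
        build_supermatrix({"g1": m1}, exclude=("g1",))


def test_exclusion_list_applied():
    m1 = _msa({"a": "ACGT", "b": "ACGT"})
    m2 = _msa({"a": "GGCC", "b": "GGCC"})
    sm = build_supermatrix({"g1": m1, "accD": m2}, exclude=("accD",))
    assert list(sm.gene_map) == ["g1"]


def test_three_taxon_closed_form():
    D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
    tree = nj_tree(D, ["A", "B", "C"])
    lengths = {c.name: c.length for c in tree.children}
    assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 7.0})


def _additive_distance(tree_nwk: str, taxa: list[str]) -> np.ndarray:
    """Path-length matrix of a tree (test-side oracle)."""
    root = parse_newick(tree_nwk)
    paths = {}

    def walk(node, acc):
        if node.is_leaf():
            paths[node.name] = acc
        for child in node.children:
            # key each edge by its child node: sibling edges with equal
            # lengths must not compare as a shared path prefix
            walk(child, acc + [(id(child), child.length)])

    walk(root, [])
    n = len(taxa)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = paths[taxa[i]], paths[taxa[j]]
        shared = 0
        for (na, _), (nb, _) in zip(pa, pb):
            if na == nb:
                shared += 1
            else:
                break
        d = sum(l for _, l in pa[shared:]) + sum(l for _, l in pb[shared:])
        D[i, j] = D[j, i] = d
    return D


@pytest.mark.parametrize(
    "newick",
    [
        "((A:2,B:3):1,(C:4,D:5):2);",
        "(((A:1,B:1):1,C:2.5):1,(D:2,E:1.5):0.5);",
        "((A:1,(B:1,C:1):0.7):0.6,((D:1,E:1):0.5,(F:1,G:1):0.4):0.3,H:2);",
    ],
)
def test_nj_recovers_generating_topology_from_additive_distances(newick):
    root = parse_newick(newick)
    taxa = sorted(root.leaves())
    D = _additive_distance(newick, taxa)
    tree = nj_tree(D, taxa)
    want = bipartitions_of_newick(newick, taxa)
    assert set(bipartitions(tree)) == want


def bipartitions_of_newick(newick: str, taxa: list[str]) -> set[frozenset]:
    root = parse_newick(newick)
    allt = frozenset(taxa)
    anchor = min(allt)
    out = set()

    def visit(node):
        below = frozenset(node.leaves())
        if node.children and node is not root:
            side = below if anchor not in below else allt - below
            if 1 < len(side) < len(allt) - 1:
                out.add(side)
        for c in node.children:
            visit(c)

    visit(root)
    return out


def test_nj_exhaustive_check_on_random_additive_trees():
    """Random additive matrices (n<=8): NJ's topology must be the unique
    additive-consistent one among all topologies scored by least squares on
    their bipartition structure — checked via perfect path-length match."""
    rng = random.Random(17)
    for _ in range(10):
        n = rng.randint(4, 8)
        taxa = [f"t{i}" for i in range(n)]
        # random binary tree via sequential attachment
        newick = _random_tree(rng, taxa)
        D = _additive_distance(newick, taxa)
        tree = nj_tree(D, taxa)
        assert set(bipartitions(tree)) == bipartitions_of_newick(newick, taxa)


def _random_tree(rng: random.Random, taxa: list[str]) -> str:
    nodes = [f"{t}:{rng.randint(1, 9)}" for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.randint(1, 9)}")
    return f"({','.join(nodes)});"


def test_negative_branch_lengths_clamped():
    D = np.array(
        [[0.0, 0.1, 0.4, 0.5],
         [0.1, 0.0, 0.45, 0.55],
         [0.4, 0.45, 0.0, 0.2],
         [0.5, 0.55, 0.2, 0.0]]
    )
    tree = nj_tree(D, ["a", "b", "c", "d"])

    def walk(node):
        assert node.length >= 0.0
        for c in node.children:
            walk(c)

    walk(tree)


def test_jc_distance_properties():
    rows = {
        "a": "ACGTACGTACGTACGTACGT",
        "b": "ACGTACGTACGTACGTACGT",
        "c": "ACGTACGTACGAACGTACGT",
        "d": "TGCA" * 5,
    }
    sm = build_supermatrix({"g": _msa(rows)})
    D = jc_distance_matrix(sm)
    ia, ib, ic, id_ = (sm.taxa.index(t) for t in "abcd")
    assert D[ia, ib] == 0.0
    assert 0 < D[ia, ic] < D[ia, id_] or math.isinf(D[ia, id_])
    assert math.isinf(D[ia, id_])  # 100% difference saturates JC


def test_jc_excludes_gap_sites_pairwise():
    rows = {"a": "ACGT----ACGT", "b": "ACGTGGGGACGT", "c": "ACGTGGGGACGA"}
    sm = build_supermatrix({"g": _msa(rows)})
    D = jc_distance_matrix(sm)
    ia, ib, ic = (sm.taxa.index(t) for t in "abc")
    assert D[ia, ib] == 0.0  # gapped block ignored
    assert D[ib, ic] > 0.0


def test_zero_variation_bootstrap_all_supports_100():
    rows = {f"s{i}": "ACGTACGTACGTACGT" for i in range(6)}
    sm = build_supermatrix({"g": _msa(rows)})
    tree, skipped = bootstrap_support(sm, replicates=25, seed=3)
    assert skipped == 0
    supports = [n.support for n in bipartitions(tree).values()]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_bit_reproducible_for_fixed_seed(cohort_msas):
    msas = {g: m for g, m in cohort_msas.items() if m is not None}
    sm = build_supermatrix(msas)
    t1, _ = bootstrap_support(sm, replicates=30, seed=11)
    t2, _ = bootstrap_support(sm, replicates=30, seed=11)
    s1 = {frozenset(k): v.support for k, v in bipartitions(t1).items()}
    s2 = {frozenset(k): v.support for k, v in bipartitions(t2).items()}
    assert s1 == s2
    t3, _ = bootstrap_support(sm, replicates=30, seed=12)
    assert to_newick(t3) == to_newick(t1)  # same point estimate, seed-free


def test_monophyly_queries():
    tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    ok, bip = is_monophyletic(tree, {"A", "B"})
    assert ok
    ok2, _ = is_monophyletic(tree, {"A", "C"})
    assert not ok2
    ok3, _ = is_monophyletic(tree, {"A"})
    assert ok3  # single taxon trivially monophyletic
    with pytest.raises(KeyError):
        is_monophyletic(tree, {"A", "Z"})


def test_newick_roundtrip_with_supports():
    """A rooted 4-taxon tree has one internal edge; both input labels (95 on
    one side, 88 on the other) describe that same bipartition, and the
    canonical representation keeps exactly one of them."""
    tree = parse_newick("((A:1,B:2)95:0.5,(C:1,D:1)88:0.25);")
    splits = bipartitions(tree)
    supports = sorted(n.support for n in splits.values())
    assert len(supports) == 1 and supports[0] in (88.0, 95.0)
    text = to_newick(tree, with_support=True)
    again = parse_newick(text)
    assert sorted(again.leaves()) == ["A", "B", "C", "D"]
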