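"""Concatenated-gene distance phylogeny with bootstrap supports.

Per-gene alignments are concatenated into a supermatrix (taxa missing a
gene are gap-padded over that gene's columns).  Pairwise distances use the
Jukes–Cantor correction by default (Kimura two-parameter available), with
gapped/ambiguous sites excluded pairwise; trees come from classic
neighbor-joining with negative branch lengths clamped to zero.  Bootstrap
supports resample supermatrix columns with replacement and report, for each
internal edge of the point-estimate tree, the percentage of replicate trees
containing the same bipartition.

Distance + NJ is used as a deliberately simple stand-in for full maximum
likelihood: the claims made on top of it (deep-clade monophyly at high
support) are robust to that substitution, and likelihood refinement is out
of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .msa import GAP, Msa

__all__ = [
    "Supermatrix",
    "TreeNode",
    "build_supermatrix",
    "jc_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "is_monophyletic",
    "bipartitions",
    "to_newick",
    "parse_newick",
]


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    gene_map: dict[str, tuple[int, int]]  # gene -> 0-based half-open column span

    @property
    def columns(self) -> int:
        return len(next(iter(self.rows.values())))

    def matrix(self) -> np.ndarray:
        """(n_taxa, columns) byte matrix for fast distance computation."""
        return np.array(
            [np.frombuffer(self.rows[t].encode(), dtype=np.uint8) for t in self.taxa]
        )


def build_supermatrix(
    msas: dict[str, Msa],
    gene_list: list[str] | None = None,
    exclude: tuple[str, ...] = (),
) -> Supermatrix:
    """Concatenate per-gene alignments in a fixed gene order.

    ``gene_list`` fixes order and selection (default: alphabetical over all
    supplied genes); genes in ``exclude`` are dropped.  A taxon absent from
    a gene gets gaps over that gene's span.  A taxon present in no gene is
    an error.
    """
    excluded = {g.lower() for g in exclude}
    if gene_list is None:
        genes = sorted(msas, key=str.lower)
    else:
        genes = [g for g in gene_list if g in msas]
    genes = [g for g in genes if g.lower() not in excluded]
    if not genes:
        raise ValueError("no genes left to concatenate")
    taxa: list[str] = []
    for g in genes:
        for name in msas[g].names:
            if name not in taxa:
                taxa.append(name)
    taxa.sort()
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    gene_map: dict[str, tuple[int, int]] = {}
    pos = 0
    for g in genes:
        msa = msas[g]
        width = msa.length
        gene_map[g] = (pos, pos + width)
        pos += width
        for t in taxa:
            pieces[t].append(msa.rows.get(t, GAP * width))
    rows = {t: "".join(pieces[t]) for t in taxa}
    for t in taxa:
        if rows[t].count(GAP) == pos:
            raise ValueError(f"taxon {t} present in zero genes")
    return Supermatrix(taxa=taxa, rows=rows, gene_map=gene_map)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

_VALID = frozenset(b"ACGT")


def _valid_mask(mat: np.ndarray) -> np.ndarray:
    valid = np.zeros_like(mat, dtype=bool)
    for c in _VALID:
        valid |= mat == c
    return valid


def jc_distance_matrix(
    sm: Supermatrix, columns: np.ndarray | None = None, model: str = "jc"
) -> np.ndarray:
    """Pairwise distance matrix (JC69 default, K2P optional).

    Sites with a gap or N in either taxon are excluded pairwise.  A
    saturated pair (p >= 3/4 for JC) yields ``inf``; the caller decides
    whether that aborts the analysis or skips a bootstrap replicate.
    """
    mat = sm.matrix()
    if columns is not None:
        mat = mat[:, columns]
    valid = _valid_mask(mat)
    n = len(sm.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            total = int(ok.sum())
            if total == 0:
                D[i, j] = D[j, i] = math.inf
                continue
            a, b = mat[i, ok], mat[j, ok]
            if model == "jc":
                p = float((a != b).sum()) / total
                if p >= 0.75:
                    d = math.inf
                else:
                    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            elif model == "k2p":
                diff = a != b
                purine = np.isin(a, (ord("A"), ord("G")))
                purine_b = np.isin(b, (ord("A"), ord("G")))
                transitions = float((diff & (purine == purine_b)).sum()) / total
                transversions = float((diff & (purine != purine_b)).sum()) / total
                w1 = 1.0 - 2.0 * transitions - transversions
                w2 = 1.0 - 2.0 * transversions
                if w1 <= 0.0 or w2 <= 0.0:
                    d = math.inf
                else:
                    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            else:
                raise ValueError(f"unknown model {model!r}")
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Unrooted tree stored with an arbitrary root; supports live on nodes
    (the support of the edge above the node)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def is_leaf(self) -> bool:
        return not self.children


def nj_tree(D: np.ndarray, taxa: list[str]) -> TreeNode:
    """Saitou–Nei neighbor joining; deterministic (first minimal Q pair by
    index order), negative branch lengths clamped to zero."""
    n = len(taxa)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        root = TreeNode()
        root.children = [
            TreeNode(name=taxa[0], length=float(D[0, 1]) / 2),
            TreeNode(name=taxa[1], length=float(D[0, 1]) / 2),
        ]
        return root
    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    D = D.astype(np.float64).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ci, cj = nodes[ai], nodes[aj]
        ci.length, cj.length = float(li), float(lj)
        parent.children = [ci, cj]
        new_index = len(nodes)
        nodes.append(parent)
        newD = np.zeros((len(nodes), len(nodes)))
        newD[: len(D), : len(D)] = D
        for k in active:
            if k in (ai, aj):
                continue
            d = 0.5 * (D[ai, k] + D[aj, k] - dij)
            newD[new_index, k] = newD[k, new_index] = max(d, 0.0)
        D = newD
        active = [k for k in active if k not in (ai, aj)] + [new_index]
    # join the last three nodes on a central vertex (closed-form lengths)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = float(max(ln, 0.0))
        root.children.append(nodes[idx])
    return root


def bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Internal-edge bipartitions, each canonicalized as the leaf set on the
    child side of the edge that excludes the lexicographically smallest
    taxon (so the representation is rooting-invariant)."""
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    out: dict[frozenset[str], TreeNode] = {}

    def visit(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])  # type: ignore[list-item]
        below = frozenset().union(*(visit(c) for c in node.children))
        side = below if anchor not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            out[side] = node
        return below

    for child in tree.children:
        visit(child)
    return out


def to_newick(tree: TreeNode, with_support: bool = False) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return f"{node.name}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in node.children)
        label = ""
        if with_support and node.support is not None:
            label = f"{node.support:g}"
        return f"({inner}){label}:{node.length:.6f}"

    inner = ",".join(fmt(c) for c in tree.children)
    return f"({inner});"


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;:]+(?::[0-9.eE+-]+)?")


def parse_newick(text: str) -> TreeNode:
    """Minimal newick parser (names, branch lengths, internal labels)."""
    pos = 0
    text = text.strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        m = re.match(r"[^(),;:]*", text[pos:])
        label = m.group(0)
        pos += len(label)
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(text) and text[pos] == ":":
            m2 = re.match(r":([0-9.eE+-]+)", text[pos:])
            node.length = float(m2.group(1))
            pos += m2.end()
        return node

    root = parse_node()
    return root


def bootstrap_support(
    sm: Supermatrix,
    replicates: int = 500,
    seed: int = 0,
    model: str = "jc",
) -> tuple[TreeNode, int]:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``replicates`` times; replicates
    with non-finite distances (saturation/empty overlap) are skipped and
    counted.  Returns (tree, n_skipped); supports are percentages of the
    *successful* replicates.
    """
    D = jc_distance_matrix(sm, model=model)
    if not np.all(np.isfinite(D)):
        raise ValueError("point-estimate distances are not all finite")
    tree = nj_tree(D, sm.taxa)
    splits = bipartitions(tree)
    counts = {split: 0 for split in splits}
    rng = np.random.default_rng(seed)
    ncols = sm.columns
    skipped = 0
    done = 0
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        Db = jc_distance_matrix(sm, columns=cols, model=model)
        if not np.all(np.isfinite(Db)):
            skipped += 1
            continue
        rep_splits = bipartitions(nj_tree(Db, sm.taxa))
        done += 1
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in splits.items():
        node.support = 100.0 * counts[split] / done if done else float("nan")
    return tree, skipped


def is_monophyletic(
    tree: TreeNode, taxa_subset: set[str] | frozenset[str]
) -> tuple[bool, frozenset[str] | None]:
    """True when some edge separates exactly ``taxa_subset`` from the rest.

    Subsets of size 1 or n-1 (and the full set) are trivially monophyletic
    on an unrooted tree.
    """
    leaves = frozenset(tree.leaves())
    subset = frozenset(taxa_subset)
    unknown = subset - leaves
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    if len(subset) in (0, 1, len(leaves) - 1, len(leaves)):
        return True, None
    anchor = min(leaves)
    canonical = subset if anchor not in subset else leaves - subset
    splits = bipartitions(tree)
    if canonical in splits:
        return True, canonical
    return False, None
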