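"""Progressive multiple sequence alignment.

A deliberately simple, deterministic progressive aligner in the ClustalW
mould: pairwise global-alignment identities give a distance matrix, a UPGMA
guide tree fixes the merge order, and profiles are merged with the same
affine-gap dynamic programme used for pairs, scoring column pairs by the
expected substitution score between their residue frequency vectors (gaps
score zero against everything).  Input order and fixed scoring make the
output bit-reproducible; an externally computed alignment can be supplied
instead wherever an :class:`Msa` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .alignment import NUCLEOTIDE_SCORING, Scoring, _dp_matrices, global_align

__all__ = ["Msa", "progressive_msa", "read_fasta_msa", "write_fasta_msa"]

GAP = "-"


@dataclass
class Msa:
    """A multiple alignment: equal-length gapped rows keyed by species."""

    names: list[str]
    rows: dict[str, str]
    alphabet: str = "nucleotide"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least two rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        cols = self.length
        for j in range(cols):
            if all(self.rows[n][j] == GAP for n in self.names):
                raise ValueError(f"all-gap column {j}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def column(self, j: int) -> dict[str, str]:
        return {n: self.rows[n][j] for n in self.names}

    def ungapped(self, name: str) -> str:
        return self.rows[name].replace(GAP, "")

    def gap_matrix(self) -> np.ndarray:
        """(n_rows, n_cols) boolean matrix of gap positions (row order =
        ``names``)."""
        return np.array(
            [[c == GAP for c in self.rows[n]] for n in self.names], dtype=bool
        )


def _pairwise_distance(
    seqs: dict[str, str], scoring: Scoring, method: str = "kmer"
) -> tuple[list[str], np.ndarray]:
    """Guide-tree distances.

    ``kmer`` (default) is the Jaccard distance on 8-mer sets — cheap and
    entirely adequate for ordering profile merges; ``alignment`` uses full
    pairwise global-alignment identity instead.
    """
    names = list(seqs)
    n = len(names)
    D = np.zeros((n, n))
    if method == "kmer":
        k = 8
        sets = {m: {seqs[m][i : i + k] for i in range(max(1, len(seqs[m]) - k + 1))} for m in names}
        for i in range(n):
            for j in range(i + 1, n):
                a, b = sets[names[i]], sets[names[j]]
                union = len(a | b)
                d = 1.0 - (len(a & b) / union if union else 1.0)
                D[i, j] = D[j, i] = d
        return names, D
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[names[i]] == seqs[names[j]]:
                d = 0.0
            else:
                d = 1.0 - global_align(seqs[names[i]], seqs[names[j]], scoring).identity_pct / 100.0
            D[i, j] = D[j, i] = d
    return names, D


def _profile_freq(rows: list[str], scoring: Scoring) -> np.ndarray:
    """(columns, |alphabet|) residue frequency matrix; gaps contribute no
    mass, so columns with gaps score proportionally less."""
    alpha = {c: i for i, c in enumerate(scoring.alphabet)}
    ncol = len(rows[0])
    F = np.zeros((ncol, len(alpha)), dtype=np.float64)
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                F[j, alpha[c]] += 1.0
    return F / len(rows)


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], scoring: Scoring
) -> tuple[list[str], list[str]]:
    FA = _profile_freq(rows_a, scoring)
    FB = _profile_freq(rows_b, scoring)
    table = scoring.lookup().astype(np.float64)
    S = FA @ table @ FB.T
    M, X, Y, ptr, _ = _dp_matrices(S, scoring.gap_open, scoring.gap_extend, local=False)
    finals = (M[-1], X[-1], Y[-1])
    state = int(np.argmax(finals))
    # traceback over profile columns
    i, j = S.shape
    ops: list[str] = []  # 'M' both advance, 'X' only A, 'Y' only B
    while i > 0 or j > 0:
        code = ptr[i, j]
        if state == 0:
            ops.append("M")
            i, j = i - 1, j - 1
            state = code & 3
        elif state == 1:
            ops.append("X")
            i -= 1
            state = (code >> 2) & 3
        else:
            ops.append("Y")
            j -= 1
            state = (code >> 4) & 3
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in ("M", "Y"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def _strip_all_gap_columns(names: list[str], rows: dict[str, str]) -> dict[str, str]:
    length = len(next(iter(rows.values())))
    keep = [
        j for j in range(length) if any(rows[n][j] != GAP for n in names)
    ]
    return {n: "".join(rows[n][j] for j in keep) for n in names}


def progressive_msa(
    seqs: dict[str, str],
    guide: "object | None" = None,
    scoring: Scoring | None = None,
    alphabet: str = "nucleotide",
    guide_distance: str = "kmer",
) -> Msa:
    """Align two or more sequences progressively.

    ``guide`` may be a precomputed merge order (scipy linkage-style list of
    (i, j) leaf/cluster index pairs) — by default a UPGMA tree on pairwise
    distances (``guide_distance``: 8-mer Jaccard, or ``alignment`` for full
    DP identity) decides it.  With exactly two sequences the result is the
    optimal pairwise alignment.
    """
    scoring = scoring or NUCLEOTIDE_SCORING
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    for name, s in seqs.items():
        if not s:
            raise ValueError(f"{name}: empty sequence")
        scoring.encode(s.upper())  # alphabet check
    names = list(seqs)
    if len(seqs) == 2:
        a, b = names
        res = global_align(seqs[a], seqs[b], scoring)
        return Msa(names=names, rows={a: res.aligned_a, b: res.aligned_b}, alphabet=alphabet)
    upper = {n: s.upper() for n, s in seqs.items()}
    if guide is None:
        order_names, D = _pairwise_distance(upper, scoring, method=guide_distance)
        Z = linkage(squareform(D, checks=False), method="average")
        merges = [(int(row[0]), int(row[1])) for row in Z]
    else:
        order_names = names
        merges = list(guide)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([order_names[i]], [upper[order_names[i]]]) for i in range(len(order_names))
    }
    nxt = len(order_names)
    for ia, ib in merges:
        names_a, rows_a = clusters.pop(ia)
        names_b, rows_b = clusters.pop(ib)
        merged_a, merged_b = _merge_profiles(rows_a, rows_b, scoring)
        clusters[nxt] = (names_a + names_b, merged_a + merged_b)
        nxt += 1
    (final_names, final_rows), = clusters.values()
    rows = dict(zip(final_names, final_rows))
    rows = _strip_all_gap_columns(final_names, rows)
    return Msa(names=[n for n in names], rows=rows, alphabet=alphabet)


def read_fasta_msa(path: str | Path, alphabet: str = "nucleotide") -> Msa:
    """Load an externally produced alignment from aligned FASTA."""
    from Bio import SeqIO

    rows = {}
    names = []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows[rec.id] = str(rec.seq).upper()
    return Msa(names=names, rows=rows, alphabet=alphabet)


def write_fasta_msa(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in msa.names:
            fh.write(f">{name}\n{msa.rows[name]}\n")
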