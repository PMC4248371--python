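"""Pairwise alignment core and gene-identity classification.

Global alignment is Needleman–Wunsch/Gotoh with affine gaps (a gap of
length n costs ``gap_open + (n-1)·gap_extend``); local alignment is the
Smith–Waterman analogue.  The dynamic programme is computed row-wise with
numpy; the horizontal gap state within a row is resolved with a running
prefix maximum, so each row costs O(m) vector work.  Traceback pointers are
packed into one uint8 matrix (2 bits per state) and tie-breaks are fixed —
diagonal over up over left — so alignments are deterministic.

Percent identity is matches over all alignment columns, gap columns
included; this deliberately penalizes indel-rich genes (an ungapped-columns
mode is available as a switch since other tools report that convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Scoring",
    "NUCLEOTIDE_SCORING",
    "PROTEIN_SCORING",
    "AlignmentResult",
    "global_align",
    "local_align",
    "identity_matrix",
    "classify_divergence",
    "DivergenceCall",
    "identity_bins",
]

_NEG = -1e9

NUC_ALPHABET = "ACGTN"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


def _blosum62() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = float(mat[a, b])
    return out


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring scheme.

    ``matrix`` overrides match/mismatch with a full substitution matrix
    (protein mode).  ``alphabet`` is the set of residues accepted in input
    sequences; N (nucleotide) and X (protein) score 0 against everything.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -10.0
    gap_extend: float = -0.5
    alphabet: str = NUC_ALPHABET
    wildcard: str = "N"  # scores 0 against everything (ignored with a matrix)
    matrix: dict[tuple[str, str], float] | None = None
    gapped_identity: bool = True  # identity denominator includes gap columns

    def lookup(self) -> np.ndarray:
        """(len(alphabet), len(alphabet)) substitution score table."""
        n = len(self.alphabet)
        table = np.full((n, n), self.mismatch, dtype=np.float32)
        np.fill_diagonal(table, self.match)
        if self.matrix is not None:
            for i, a in enumerate(self.alphabet):
                for j, b in enumerate(self.alphabet):
                    table[i, j] = self.matrix.get((a, b), self.matrix.get((b, a), 0.0))
            return table
        wild = [i for i, c in enumerate(self.alphabet) if c in self.wildcard]
        for i in wild:
            table[i, :] = 0.0
            table[:, i] = 0.0
        return table

    def encode(self, seq: str) -> np.ndarray:
        idx = {c: i for i, c in enumerate(self.alphabet)}
        try:
            return np.fromiter((idx[c] for c in seq), dtype=np.int16, count=len(seq))
        except KeyError as exc:
            raise ValueError(f"residue {exc} not in alphabet {self.alphabet!r}") from exc


NUCLEOTIDE_SCORING = Scoring()
PROTEIN_SCORING = Scoring(
    gap_open=-11.0, gap_extend=-1.0, alphabet=AA_ALPHABET, wildcard="X", matrix=None
)


def protein_scoring() -> Scoring:
    """BLOSUM62 with -11/-1 affine gaps (loaded lazily from Biopython)."""
    return replace(PROTEIN_SCORING, matrix=_blosum62())


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    columns: int
    identity_pct: float
    # local alignment extras: 0-based half-open spans in the input sequences
    query_span: tuple[int, int] | None = None
    subject_span: tuple[int, int] | None = None


def _identity(aligned_a: str, aligned_b: str, gapped: bool = True) -> tuple[int, int, float]:
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    if gapped:
        columns = len(aligned_a)
    else:
        columns = sum(1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-")
    pct = 100.0 * matches / columns if columns else 0.0
    return matches, columns, pct


# pointer codes packed in one uint8: bits 0-1 M-source, 2-3 X-source, 4-5 Y-source
_FROM_M, _FROM_X, _FROM_Y, _FROM_STOP = 0, 1, 2, 3


def _pack(pm, px, py):
    return (pm | (px << 2) | (py << 4)).astype(np.uint8)


def _dp_matrices(S: np.ndarray, gap_open: float, gap_extend: float, local: bool):
    """Shared Gotoh forward pass.

    Returns (M, X, Y) final rows plus the packed pointer matrix and, for
    local mode, the full M matrix for locating maxima.  X = gap in the
    second sequence (vertical move), Y = gap in the first (horizontal).
    """
    n, m = S.shape
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    M = np.full(m + 1, _NEG, dtype=np.float64)
    X = np.full(m + 1, _NEG, dtype=np.float64)
    Y = np.full(m + 1, _NEG, dtype=np.float64)
    M[0] = 0.0
    if not local:
        js = np.arange(1, m + 1)
        Y[1:] = gap_open + (js - 1) * gap_extend
        ptr[0, 1:] = _pack(np.zeros(m, np.uint8), np.zeros(m, np.uint8),
                           np.full(m, _FROM_Y, np.uint8))
        ptr[0, 1] = _pack(np.array(0, np.uint8), np.array(0, np.uint8),
                          np.array(_FROM_M, np.uint8))
    else:
        M[:] = 0.0
    Mfull = np.zeros((n + 1, m + 1), dtype=np.float64) if local else None
    ext = gap_extend
    jidx = np.arange(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        prevM, prevX, prevY = M, X, Y
        # M: diagonal from best of previous row, priority M > X > Y on ties
        stacked = np.vstack((prevM[:-1], prevX[:-1], prevY[:-1]))
        pm = np.argmax(stacked, axis=0).astype(np.uint8)  # argmax takes first max
        bestPrev = stacked[pm, np.arange(m)]
        newM = np.empty(m + 1)
        newM[0] = _NEG
        newM[1:] = S[i - 1] + bestPrev
        if local:
            stop = newM[1:] < 0
            newM[1:][stop] = 0.0
            pm = np.where(stop, np.uint8(_FROM_STOP), pm)
        # X: vertical gap, from M/Y (open) or X (extend) of the previous row
        open_from = np.where(prevM >= prevY, prevM, prevY)
        px_open = np.where(prevM >= prevY, np.uint8(_FROM_M), np.uint8(_FROM_Y))
        extend = prevX + ext
        opened = open_from + gap_open
        newX = np.where(opened >= extend, opened, extend)
        px = np.where(opened >= extend, px_open, np.uint8(_FROM_X))
        # Y: horizontal gap via prefix max over the current row
        src = np.where(newM >= newX, newM, newX)
        py_src = np.where(newM >= newX, np.uint8(_FROM_M), np.uint8(_FROM_X))
        g = src + gap_open - ext * (jidx + 1)  # candidate openings at column j+1
        z = np.maximum.accumulate(g[:-1])
        newY = np.full(m + 1, _NEG)
        newY[1:] = z + ext * jidx[1:]
        fresh = g[:-1] >= np.concatenate(([_NEG], z[:-1]))  # column opened here
        open_pred = py_src[:-1]
        py = np.zeros(m + 1, dtype=np.uint8)
        py[1:] = np.where(fresh, open_pred, np.uint8(_FROM_Y))
        # the "opened here" pointer must reference the column the gap opened
        # from; during traceback a fresh Y consumes exactly one gap, so the
        # predecessor state is looked up at (i, j-1) directly.
        ptr[i] = _pack(pm_row(pm, m), px.astype(np.uint8), py)
        M, X, Y = newM, newX, newY
        if local:
            Mfull[i] = newM
    return M, X, Y, ptr, Mfull


def pm_row(pm: np.ndarray, m: int) -> np.ndarray:
    row = np.zeros(m + 1, dtype=np.uint8)
    row[1:] = pm
    return row


def _traceback_global(a: str, b: str, ptr: np.ndarray, end_state: int):
    i, j = len(a), len(b)
    out_a: list[str] = []
    out_b: list[str] = []
    state = end_state
    while i > 0 or j > 0:
        code = ptr[i, j]
        if state == 0:  # M: consumed a[i-1], b[j-1]
            prev = code & 3
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:  # X: gap in b, consumed a[i-1]
            prev = (code >> 2) & 3
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            state = prev
        else:  # Y: gap in a, consumed b[j-1]
            prev = (code >> 4) & 3
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            state = prev
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def global_align(a: str, b: str, scoring: Scoring | None = None) -> AlignmentResult:
    """Optimal global alignment of two sequences (affine gaps).

    Deterministic traceback with the tie-break diagonal > up (gap in ``b``)
    > left (gap in ``a``).
    """
    scoring = scoring or NUCLEOTIDE_SCORING
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = scoring.encode(a.upper()), scoring.encode(b.upper())
    table = scoring.lookup()
    S = table[np.ix_(ea, eb)].astype(np.float64)
    M, X, Y, ptr, _ = _dp_matrices(S, scoring.gap_open, scoring.gap_extend, local=False)
    finals = (M[-1], X[-1], Y[-1])
    end_state = int(np.argmax(finals))  # priority M > X > Y
    score = float(finals[end_state])
    aligned_a, aligned_b = _traceback_global(a.upper(), b.upper(), ptr, end_state)
    matches, columns, pct = _identity(aligned_a, aligned_b, scoring.gapped_identity)
    return AlignmentResult(aligned_a, aligned_b, score, matches, columns, pct)


def _traceback_local(a, b, ptr, start_i, start_j, Mfull):
    i, j = start_i, start_j
    out_a: list[str] = []
    out_b: list[str] = []
    state = 0
    while i > 0 and j > 0:
        code = ptr[i, j]
        if state == 0:
            prev = code & 3
            if prev == _FROM_STOP and Mfull[i, j] == 0.0 and not out_a:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if prev == _FROM_STOP:
                break
            state = prev
        elif state == 1:
            prev = (code >> 2) & 3
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            state = prev
        else:
            prev = (code >> 4) & 3
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            state = prev
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def local_align(
    query: str,
    subject: str,
    scoring: Scoring | None = None,
    min_score: float = 25.0,
    max_hits: int = 50,
) -> list[AlignmentResult]:
    """Smith–Waterman local hits with score >= ``min_score``.

    Hits are reported best-score first and must not overlap an already
    accepted hit on the subject.
    """
    scoring = scoring or NUCLEOTIDE_SCORING
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q, s = query.upper(), subject.upper()
    eq, es = scoring.encode(q), scoring.encode(s)
    table = scoring.lookup()
    S = table[np.ix_(eq, es)].astype(np.float64)
    _, _, _, ptr, Mfull = _dp_matrices(S, scoring.gap_open, scoring.gap_extend, local=True)
    order = np.dstack(np.unravel_index(np.argsort(Mfull, axis=None)[::-1], Mfull.shape))[0]
    hits: list[AlignmentResult] = []
    used: list[tuple[int, int]] = []
    for i, j in order:
        sc = Mfull[i, j]
        if sc < min_score or len(hits) >= max_hits:
            break
        if any(lo < j <= hi for lo, hi in used):
            continue
        aligned_q, aligned_s, qi, sj = _traceback_local(q, s, ptr, int(i), int(j), Mfull)
        if not aligned_q:
            continue
        span = (sj, int(j))
        if any(span[0] < hi and lo < span[1] for lo, hi in used):
            continue
        used.append(span)
        matches, columns, pct = _identity(aligned_q, aligned_s, scoring.gapped_identity)
        hits.append(
            AlignmentResult(
                aligned_q, aligned_s, float(sc), matches, columns, pct,
                query_span=(qi, int(i)), subject_span=span,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# identity matrices and divergence classification
# ---------------------------------------------------------------------------


def species_pairs(species: list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(species), 2))


def identity_matrix(
    gene_sets: dict[str, dict[str, str]],
    scoring: Scoring | None = None,
    max_missing: int | None = None,
) -> "pandas.DataFrame":  # noqa: F821
    """Pairwise percent identity per gene across species.

    ``gene_sets`` maps species -> {gene name -> sequence}; gene names are
    matched case-insensitively (tRNA anticodon suffixes stay significant).
    Returns a genes x pairs DataFrame (pair columns "A|B", species sorted),
    NaN where a gene is missing in either species; genes missing in more
    than ``max_missing`` species are dropped with a warning attribute.
    """
    import pandas as pd

    scoring = scoring or NUCLEOTIDE_SCORING
    species = sorted(gene_sets)
    canon: dict[str, str] = {}
    per_species: dict[str, dict[str, str]] = {}
    for sp, genes in gene_sets.items():
        per_species[sp] = {}
        for name, seq in genes.items():
            canon.setdefault(name.lower(), name)
            per_species[sp][name.lower()] = seq
    genes = sorted(canon)
    pairs = species_pairs(species)
    dropped = []
    rows = {}
    for gene in genes:
        present = [sp for sp in species if gene in per_species[sp]]
        missing = len(species) - len(present)
        if max_missing is not None and missing > max_missing:
            dropped.append(canon[gene])
            continue
        row = {}
        for sa, sb in pairs:
            key = f"{sa}|{sb}"
            if gene in per_species[sa] and gene in per_species[sb]:
                x, y = per_species[sa][gene], per_species[sb][gene]
                if x == y:  # fast path: identical orthologues
                    row[key] = 100.0
                else:
                    row[key] = global_align(x, y, scoring).identity_pct
            else:
                row[key] = np.nan
        rows[canon[gene]] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(sorted(rows, key=str.lower))
    df.attrs["dropped_genes"] = dropped
    return df


def identity_bins(pct: float) -> str:
    """5%-step identity bin label from 80 up (supplementary-table style)."""
    if pct >= 100.0:
        return "100"
    if pct < 80.0:
        return "<80"
    lo = int(pct // 5 * 5)
    return f"[{lo},{lo + 5})"


@dataclass
class DivergenceCall:
    gene: str
    klass: str  # highly_conserved | highly_divergent | intermediate
    min_identity: float
    conserved_pairs: list[str]
    bins: dict[str, str]


def classify_divergence(
    matrix: "pandas.DataFrame",  # noqa: F821
    divergent_below: float = 95.0,
    conserved_at: float = 100.0,
) -> tuple[dict[str, DivergenceCall], dict[str, int]]:
    """Per-gene divergence classes plus per-pair counts of fully conserved
    genes.

    A gene is highly divergent when any pair falls below ``divergent_below``;
    it is conserved *for a pair* when that pair's identity equals
    ``conserved_at``; genes conserved in every pair are highly conserved.
    """
    calls: dict[str, DivergenceCall] = {}
    pair_counts: dict[str, int] = {col: 0 for col in matrix.columns}
    for gene, row in matrix.iterrows():
        vals = row.dropna()
        if vals.empty:
            continue
        conserved_pairs = [p for p, v in vals.items() if v >= conserved_at]
        for p in conserved_pairs:
            pair_counts[p] += 1
        min_identity = float(vals.min())
        if min_identity < divergent_below:
            klass = "highly_divergent"
        elif len(conserved_pairs) == len(vals):
            klass = "highly_conserved"
        else:
            klass = "intermediate"
        calls[gene] = DivergenceCall(
            gene=gene,
            klass=klass,
            min_identity=min_identity,
            conserved_pairs=conserved_pairs,
            bins={p: identity_bins(float(v)) for p, v in vals.items()},
        )
    return calls, pair_counts
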