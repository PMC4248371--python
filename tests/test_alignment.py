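"""Pairwise alignment core: optimality, identity, local hits, divergence
classification."""

from __future__ import annotations

import random
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcomp.alignment import (
    NUCLEOTIDE_SCORING,
    Scoring,
    classify_divergence,
    global_align,
    identity_bins,
    identity_matrix,
    local_align,
    protein_scoring,
)

SC = NUCLEOTIDE_SCORING


def oracle_score(a: str, b: str, scoring: Scoring = SC) -> float:
    """Independent affine-gap optimum: plain memoized recursion over
    (i, j, state) — structurally unlike the vectorized row DP it checks."""
    match, mismatch = scoring.match, scoring.mismatch
    open_, ext = scoring.gap_open, scoring.gap_extend

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else -1e18
        options = []
        if state == "M" and i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            options = [best(i - 1, j - 1, p) + s for p in "MXY"]
        elif state == "X" and i > 0:  # gap in b
            options = [
                best(i - 1, j, "M") + open_,
                best(i - 1, j, "Y") + open_,
                best(i - 1, j, "X") + ext,
            ]
        elif state == "Y" and j > 0:  # gap in a
            options = [
                best(i, j - 1, "M") + open_,
                best(i, j - 1, "X") + open_,
                best(i, j - 1, "Y") + ext,
            ]
        return max(options) if options else -1e18

    return max(best(len(a), len(b), s) for s in "MXY")


def enumerate_all_alignments(a: str, b: str):
    """Literal enumeration of every gapped alignment (tiny inputs only)."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for x, y in enumerate_all_alignments(a[:-1], b):
            yield (x + a[-1], y + "-")
    if b:
        for x, y in enumerate_all_alignments(a, b[:-1]):
            yield (x + "-", y + b[-1])
    if a and b:
        for x, y in enumerate_all_alignments(a[:-1], b[:-1]):
            yield (x + a[-1], y + b[-1])


def score_alignment(x: str, y: str, scoring: Scoring = SC) -> float:
    total, state = 0.0, None
    for cx, cy in zip(x, y):
        if cx == "-" or cy == "-":
            new_state = "gx" if cy == "-" else "gy"
            total += scoring.gap_extend if state == new_state else scoring.gap_open
            state = new_state
        else:
            total += scoring.match if cx == cy else scoring.mismatch
            state = None
    return total


def test_memo_oracle_agrees_with_full_enumeration():
    """The recursion oracle itself is validated against literal enumeration
    of all alignments for lengths <= 5."""
    rng = random.Random(0)
    for _ in range(40):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 5)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 5)))
        brute = max(score_alignment(x, y) for x, y in enumerate_all_alignments(a, b))
        assert oracle_score(a, b) == pytest.approx(brute)


def test_identity_and_gap_free_self_alignment():
    r = global_align("ACGTACGT", "ACGTACGT")
    assert r.identity_pct == 100.0 and "-" not in r.aligned_a + r.aligned_b
    assert global_align("ACGT", "ACGA").identity_pct == 75.0


def test_alignment_restores_inputs_and_score_consistent():
    rng = random.Random(5)
    for _ in range(100):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 40)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 40)))
        r = global_align(a, b)
        assert r.aligned_a.replace("-", "") == a
        assert r.aligned_b.replace("-", "") == b
        assert score_alignment(r.aligned_a, r.aligned_b) == pytest.approx(r.score)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=12),
    st.text(alphabet="ACGT", min_size=1, max_size=12),
)
def test_identity_symmetric_under_swap(a, b):
    assert global_align(a, b).identity_pct == pytest.approx(
        global_align(b, a).identity_pct
    )


def test_substitutions_never_increase_identity():
    rng = random.Random(9)
    base = "".join(rng.choice("ACGT") for _ in range(300))
    mutated = list(base)
    last = 100.0
    positions = rng.sample(range(300), 60)
    for i, pos in enumerate(positions):
        mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        if i % 10 == 9:
            ident = global_align(base, "".join(mutated)).identity_pct
            assert ident <= last + 1e-9
            last = ident


def test_closed_form_identity_for_planted_substitutions():
    rng = random.Random(13)
    L, d = 600, 17
    base = "".join(rng.choice("ACGT") for _ in range(L))
    mutated = list(base)
    for pos in rng.sample(range(L), d):
        mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
    r = global_align(base, "".join(mutated))
    assert r.identity_pct == pytest.approx(100.0 * (L - d) / L)


def test_protein_alignment_blosum62():
    ps = protein_scoring()
    r = global_align("MKWVTFISLLLLFSSAYS", "MKWVTFISLLLLFSSAYS", ps)
    assert r.identity_pct == 100.0
    r2 = global_align("MKWVTF", "MKWTF", ps)
    assert r2.columns == 6 and r2.matches == 5


def test_alphabet_violation_raises():
    with pytest.raises(ValueError, match="alphabet"):
        global_align("ACGU", "ACGT")


def test_local_embedded_query_full_length_hit():
    rng = random.Random(21)
    subject = "".join(rng.choice("ACGT") for _ in range(1500))
    query = subject[600:740]
    hits = local_align(query, subject, min_score=50)
    assert hits and hits[0].identity_pct == 100.0
    assert hits[0].subject_span == (600, 740)
    assert hits[0].query_span == (0, 140)


def test_shuffled_query_scores_below_calibrated_null():
    """A shuffled query should not reach the score of the embedded original;
    the threshold is calibrated as the max over shuffled replicates."""
    rng = random.Random(33)
    subject = "".join(rng.choice("ACGT") for _ in range(1200))
    query = subject[300:420]
    null_best = 0.0
    for _ in range(60):
        shuffled = list(query)
        rng.shuffle(shuffled)
        hits = local_align("".join(shuffled), subject, min_score=15)
        if hits:
            null_best = max(null_best, hits[0].score)
    real = local_align(query, subject, min_score=15)[0].score
    assert real > null_best
    assert not local_align("".join(rng.sample(query, len(query))), subject,
                           min_score=null_best + 1)


def test_identity_matrix_missing_genes_and_fast_path():
    sets = {
        "A": {"g1": "ACGTACGTAA", "g2": "TTTTCCCC"},
        "B": {"g1": "ACGTACGTAA", "g2": "TTTTCCCG"},
        "C": {"g1": "ACGTACGTAA"},
    }
    df = identity_matrix(sets)
    assert df.loc["g1", "A|B"] == 100.0
    assert df.loc["g2", "A|B"] == pytest.approx(87.5)
    assert np.isnan(df.loc["g2", "A|C"])
    dropped = identity_matrix(sets, max_missing=0).attrs["dropped_genes"]
    assert dropped == ["g2"]


def test_divergence_thresholds():
    import pandas as pd

    df = pd.DataFrame(
        {
            "A|B": {"divergent": 94.9, "conserved": 100.0, "middle": 99.0},
            "A|C": {"divergent": 99.0, "conserved": 100.0, "middle": 100.0},
        }
    )
    calls, counts = classify_divergence(df)
    assert calls["divergent"].klass == "highly_divergent"
    assert calls["conserved"].klass == "highly_conserved"
    assert calls["middle"].klass == "intermediate"
    assert counts == {"A|B": 1, "A|C": 2}


def test_identity_bins_labels():
    assert identity_bins(100.0) == "100"
    assert identity_bins(99.2) == "[95,100)"
    assert identity_bins(95.0) == "[95,100)"
    assert identity_bins(84.99) == "[80,85)"
    assert identity_bins(61.0) == "<80"
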