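"""De novo detection of the plastome inverted repeat and LSC/IRb/SSC/IRa
partitioning.

The detector seeds on exact k-mer matches between the genome and its
reverse complement on the doubled (circular) sequence, merges seeds along
anti-diagonals into maximal exact reverse-complementary segment pairs, and
optionally extends the best pair outwards with a bounded mismatch budget.
The two single-copy gaps between the chosen IR copies become LSC (larger)
and SSC (smaller); region order around the circle is LSC -> IRb -> SSC ->
IRa, matching the conventional plastome layout.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genbank_io import PlastomeRecord, reverse_complement

__all__ = [
    "Region",
    "QuadripartitePartition",
    "detect_inverted_repeat",
    "region_of",
    "partition_table",
]

REGION_NAMES = ("LSC", "IRb", "SSC", "IRa")


@dataclass(frozen=True)
class Region:
    """Circular genome interval, 0-based half-open; end may exceed the genome
    length for a region spanning the origin (interpret modulo length)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int, genome_length: int) -> bool:
        p = pos % genome_length
        if p < self.start:
            p += genome_length
        return self.start <= p < self.end

    def as_one_based(self, genome_length: int) -> tuple[int, int]:
        """(start, end) 1-based inclusive, start reduced modulo the length."""
        return (self.start % genome_length) + 1, ((self.end - 1) % genome_length) + 1


@dataclass(frozen=True)
class QuadripartitePartition:
    lsc: Region
    irb: Region
    ssc: Region
    ira: Region
    mismatches: int = 0

    @property
    def regions(self) -> dict[str, Region]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}

    def validate(self, record: PlastomeRecord, max_mismatch: int = 0) -> None:
        L = record.length_bp
        total = sum(r.length for r in self.regions.values())
        if total != L:
            raise ValueError(f"regions sum to {total}, genome is {L}")
        if self.ira.length != self.irb.length:
            raise ValueError("IR copies differ in length")
        a = record.slice(self.irb.start % L, self.irb.start % L + self.irb.length)
        b = record.slice(self.ira.start % L, self.ira.start % L + self.ira.length)
        mm = sum(1 for x, y in zip(a, reverse_complement(b)) if x != y)
        if mm != self.mismatches or mm > max(max_mismatch, self.mismatches):
            raise ValueError(f"IR copies disagree at {mm} positions (recorded {self.mismatches})")


def _maximal_rc_segment_pairs(seq: str, k: int, min_len: int):
    """All maximal exact reverse-complementary segment pairs of a circular
    sequence, found by k-mer seeding on the doubled string.

    Yields (start1, start2, length) with starts in doubled-string
    coordinates and segment2 = reverse complement of segment1.
    """
    L = len(seq)
    if L < 2 * k:
        return []
    doubled = seq + seq
    n = 2 * L - k + 1
    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(doubled[i : i + k], []).append(i)
    rc = reverse_complement(doubled)
    # seed (i, j): doubled[i:i+k] == reverse_complement(doubled[j:j+k])
    diagonals: dict[int, set[int]] = {}
    for j in range(n):
        kmer_rc = rc[2 * L - k - j : 2 * L - j]
        for i in index.get(kmer_rc, ()):
            diagonals.setdefault(i + j, set()).add(i)
    pairs = []
    seen = set()
    for c, starts in diagonals.items():
        run: list[int] = []
        for i in sorted(starts):
            if run and i != run[-1] + 1:
                _emit_run(run, c, k, L, min_len, pairs, seen)
                run = []
            run.append(i)
        _emit_run(run, c, k, L, min_len, pairs, seen)
    return pairs


def _emit_run(run, c, k, L, min_len, pairs, seen):
    if not run:
        return
    a, b = run[0], run[-1]
    length = b - a + k
    if length < min_len:
        return
    s1, s2 = a, c - b  # segment2 = rc(segment1), same length
    if length > L:  # the whole circle matched twice over; clamp
        length = L
    key = tuple(sorted(((s1 % L), (s2 % L)))) + (length,)
    if key in seen:
        return
    seen.add(key)
    pairs.append((s1, s2, length))


def _disjoint_on_circle(s1: int, s2: int, length: int, L: int) -> bool:
    a1, a2 = s1 % L, s2 % L
    if a1 == a2:
        return False
    lo, hi = (a1, a2) if a1 < a2 else (a2, a1)
    return lo + length <= hi and hi + length <= lo + L


def _extend_with_mismatches(seq: str, s1: int, s2: int, length: int, budget: int):
    """Greedily extend a reverse-complementary pair outwards, spending at most
    ``budget`` mismatches in total, without letting the copies collide on the
    circle.  Each flank is extended independently and trailing mismatched
    columns are trimmed back, so an extension never ends on a mismatch."""
    L = len(seq)
    comp = str.maketrans("ACGTN", "TGCAN")
    total = 0
    # extending segment1 rightwards consumes segment2's left flank; extending
    # segment1 leftwards consumes segment2's right flank
    for side in ("right", "left"):
        flags: list[bool] = []
        used = 0
        while length < L - 2:
            if side == "right":
                ns1, ns2 = s1, s2 - 1
                x = seq[(s1 + length) % L]
                y = seq[(s2 - 1) % L].translate(comp)
            else:
                ns1, ns2 = s1 - 1, s2
                x = seq[(s1 - 1) % L]
                y = seq[(s2 + length) % L].translate(comp)
            if not _disjoint_on_circle(ns1, ns2, length + 1, L):
                break
            mismatch = x != y
            if mismatch and total + used + 1 > budget:
                break
            used += mismatch
            s1, s2, length = ns1, ns2, length + 1
            flags.append(mismatch)
        while flags and flags[-1]:
            flags.pop()
            used -= 1
            length -= 1
            if side == "right":
                s2 += 1
            else:
                s1 += 1
        total += used
    return s1, s2, length, total


def detect_inverted_repeat(
    record: PlastomeRecord,
    min_len: int = 10_000,
    max_mismatch: int = 0,
    k: int = 25,
) -> QuadripartitePartition | None:
    """Find the large inverted repeat and partition the genome.

    Returns None when no disjoint reverse-complementary pair of length >=
    ``min_len`` exists ("no-IR" outcome).  With ``max_mismatch`` > 0 the
    best exact pair is extended outwards allowing up to that many
    mismatched positions between the two copies.
    """
    seq = record.sequence
    L = record.length_bp
    candidates = [
        (s1, s2, length)
        for s1, s2, length in _maximal_rc_segment_pairs(seq, k, min(min_len, k))
        if _disjoint_on_circle(s1, s2, length, L)
    ]
    if not candidates:
        return None
    # maximal length, then smallest normalized start for determinism
    candidates.sort(key=lambda t: (-t[2], min(t[0] % L, t[1] % L), max(t[0] % L, t[1] % L)))
    s1, s2, length = candidates[0]
    mismatches = 0
    if max_mismatch > 0:
        s1, s2, length, mismatches = _extend_with_mismatches(seq, s1, s2, length, max_mismatch)
    if length < min_len:
        return None
    return _partition_from_pair(s1 % L, s2 % L, length, L, mismatches)


def _partition_from_pair(
    a: int, b: int, length: int, L: int, mismatches: int
) -> QuadripartitePartition:
    if b < a:
        a, b = b, a
    gap_inner = b - (a + length)  # between copy1 end and copy2 start
    gap_outer = L - length - gap_inner - length  # wrapping gap
    # larger gap is the LSC; IRb is the copy that follows the LSC
    if gap_inner >= gap_outer:
        # LSC = (a+length .. b), IRb starts at b, SSC wraps, IRa at a
        lsc = Region(a + length, b)
        irb = Region(b, b + length)
        ssc = Region(b + length, a + L)
        ira = Region(a, a + length) if a >= b + length - L else Region(a + L, a + L + length)
        # normalize ira to follow ssc contiguously
        ira = Region(ssc.end, ssc.end + length)
    else:
        # LSC spans the wrap from copy2 end to copy1 start
        start = (b + length) % L
        lsc = Region(start, start + gap_outer)
        irb = Region(lsc.end, lsc.end + length)
        ssc = Region(irb.end, irb.end + gap_inner)
        ira = Region(ssc.end, ssc.end + length)
    return QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, mismatches=mismatches)


def region_of(partition: QuadripartitePartition, position: int, genome_length: int) -> str:
    """Region label for a 1-based genome position."""
    if not (1 <= position <= genome_length):
        raise ValueError(f"position {position} outside [1, {genome_length}]")
    pos0 = position - 1
    for name, region in partition.regions.items():
        if region.contains(pos0, genome_length):
            return name
    raise AssertionError("partition does not tile the genome")


def partition_table(records_partitions) -> "pandas.DataFrame":  # noqa: F821
    """Tidy TSV-ready table: accession, region, start, end, length (1-based)."""
    import pandas as pd

    rows = []
    for record, part in records_partitions:
        if part is None:
            rows.append({"accession": record.accession, "region": "no-IR",
                         "start": None, "end": None, "length": None})
            continue
        for name, region in part.regions.items():
            s, e = region.as_one_based(record.length_bp)
            rows.append({"accession": record.accession, "region": name,
                         "start": s, "end": e, "length": region.length})
    return pd.DataFrame(rows)
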