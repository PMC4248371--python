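"""Synthetic annotated plastomes with planted mutations and a truth log.

The generator builds a miniature circular plastome (default ~23 kb, about
ten times smaller than a real plastid genome so the full pipeline runs in
seconds) with the canonical quadripartite architecture — LSC, an exact
inverted repeat pair, SSC — and a gene roster that mirrors the features the
pipeline must handle: intronless and one/two-intron genes, tRNAs with
introns, an rRNA, IR-duplicated genes, minus-strand genes, and a
trans-spliced rps12 whose 5' exon sits in the LSC while exons II–III lie in
the IR (both copies).

A cohort of species is then evolved along a fixed genus-structured guide
tree.  All mutation events live in *ancestor coordinates* inside globally
disjoint windows (separated by a configurable buffer), which makes the
truth log exactly replayable and keeps multiple-alignment gap placement
unambiguous, so the downstream InDel catalogue can be compared to the truth
event-by-event.  The inverted repeat is held fixed during evolution (the
real IR evolves concertedly and its genes are observed to be exceptionally
conserved); substitutions and indels are confined to the single-copy
regions.

Planted (named) events default to the cohort's study conditions: a set of
genus- and species-specific insertions/deletions of realistic sizes placed
in specific genes' exons and introns, plus low-rate background
substitutions and indels on every branch.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genbank_io import (
    GeneModel,
    PlastomeRecord,
    _assign_copy_indices,
    _build_model,
    gene_sequence,
    reverse_complement,
    write_genbank,
)

__all__ = [
    "GeneSpec",
    "AncestorConfig",
    "CohortConfig",
    "SimEvent",
    "SyntheticTruth",
    "make_ancestor",
    "evolve_cohort",
    "default_cohort",
    "write_cohort",
    "DEFAULT_TREE",
    "DEFAULT_GENUS_MAP",
    "DEFAULT_OUTGROUPS",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
#: plastomes are AT-rich; all random sequence is drawn at this AT fraction
_AT_FRACTION = 0.62
_BASE_P = (_AT_FRACTION / 2, (1 - _AT_FRACTION) / 2, (1 - _AT_FRACTION) / 2, _AT_FRACTION / 2)


def _stream(seed: int, label: str) -> np.random.Generator:
    """One independent, reproducible random stream per (seed, label)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# ancestor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    """Declarative gene recipe: exon lengths with introns between them."""

    name: str
    kind: str  # CDS | tRNA | rRNA
    region: str  # LSC | IR | SSC
    strand: int = 1
    exon_lengths: tuple[int, ...] = (300,)
    intron_lengths: tuple[int, ...] = ()

    @property
    def genomic_span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


#: default roster; CDS spliced lengths are divisible by three
DEFAULT_GENES: tuple[GeneSpec, ...] = (
    GeneSpec("psbA", "CDS", "LSC", -1, (900,)),
    GeneSpec("matK", "CDS", "LSC", 1, (1200,)),
    GeneSpec("rps16", "CDS", "LSC", 1, (40, 218), (850,)),
    GeneSpec("trnK-UUU", "tRNA", "LSC", 1, (37, 35), (600,)),
    GeneSpec("accD", "CDS", "LSC", 1, (1200,)),
    GeneSpec("rbcL", "CDS", "LSC", 1, (999,)),
    GeneSpec("trnL-UAA", "tRNA", "LSC", 1, (35, 50), (500,)),
    GeneSpec("clpP", "CDS", "LSC", 1, (71, 292, 228), (500, 450)),
    GeneSpec("ycf3", "CDS", "LSC", -1, (124, 230, 153), (450, 500)),
    # rps12 is assembled separately: 5' exon in LSC, exons II-III in the IR
    GeneSpec("rrn16", "rRNA", "IR", 1, (1000,)),
    GeneSpec("trnA-UGC", "tRNA", "IR", 1, (38, 35), (700,)),
    GeneSpec("ndhB", "CDS", "IR", -1, (300, 246), (300,)),
    GeneSpec("ndhA", "CDS", "SSC", 1, (553, 539), (700,)),
    GeneSpec("ycf1", "CDS", "SSC", 1, (720,)),
    GeneSpec("rpl32", "CDS", "SSC", 1, (180,)),
)

RPS12_EXONS = (114, 232, 26)
RPS12_INTRON2 = 536


@dataclass(frozen=True)
class AncestorConfig:
    lsc_len: int = 12_000
    ir_len: int = 4_000
    ssc_len: int = 3_200
    genes: tuple[GeneSpec, ...] = DEFAULT_GENES
    include_rps12: bool = True

    @property
    def genome_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len


@dataclass
class SimEvent:
    """One mutation event in ancestor coordinates.

    ``species`` is the set of cohort members carrying the event; ``payload``
    is the inserted sequence (insertions) or the new base (substitutions).
    """

    etype: str  # substitution | insertion | deletion
    species: frozenset[str]
    gene: str | None
    region: str  # exon | intron | intergenic
    pos: int
    length: int
    payload: str | None = None
    source: str = "background"

    def window(self) -> tuple[int, int]:
        if self.etype == "deletion":
            return (self.pos, self.pos + self.length)
        return (self.pos, self.pos)


@dataclass
class SyntheticTruth:
    seed: int
    ancestor: PlastomeRecord
    region_coords: dict[str, tuple[int, int]]  # ancestor coords, 0-based half-open
    tree_newick: str
    genus_map: dict[str, str]
    outgroups: tuple[str, ...]
    species: list[str] = field(default_factory=list)
    events: list[SimEvent] = field(default_factory=list)

    def events_for(self, species: str) -> list[SimEvent]:
        return [e for e in self.events if species in e.species]

    def replay(self, species: str) -> str:
        """Apply the event log to the ancestor; must equal the emitted
        species sequence exactly."""
        seq = list(self.ancestor.sequence)
        for e in self.events:
            if species in e.species and e.etype == "substitution":
                seq[e.pos] = e.payload
        indels = sorted(
            (e for e in self.events if species in e.species and e.etype != "substitution"),
            key=lambda e: -e.pos,
        )
        for e in indels:
            if e.etype == "deletion":
                del seq[e.pos : e.pos + e.length]
            else:
                seq[e.pos : e.pos] = list(e.payload)
        return "".join(seq)

    def indel_signatures(self, gene: str, rows: set[str] | None = None):
        """Multiset of (length, gapped-row set, region) for a gene's indels,
        canonicalized the way a multiple alignment shows them: a deletion in
        S gaps S; an insertion in S gaps everyone else.  ``rows`` restricts
        the view to the species present in the alignment (an event invisible
        within those rows — carried by none or by all of them — is dropped).
        """
        rows = set(self.species) if rows is None else set(rows)
        out = []
        for e in self.events:
            if e.etype == "substitution" or e.gene != gene:
                continue
            carriers = frozenset(e.species & rows)
            gapped = carriers if e.etype == "deletion" else frozenset(rows - carriers)
            if not gapped or gapped == rows:
                continue
            out.append((e.length, gapped, e.region))
        return sorted(out, key=lambda t: (t[0], sorted(t[1]), t[2]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "genome_length": self.ancestor.length_bp,
            "region_coords": self.region_coords,
            "tree_newick": self.tree_newick,
            "genus_map": self.genus_map,
            "outgroups": list(self.outgroups),
            "species": self.species,
            "events": [
                {**asdict(e), "species": sorted(e.species)} for e in self.events
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.choice(4, size=n, p=_BASE_P))


def _random_cds(rng: np.random.Generator, n: int) -> str:
    """Random CDS: ATG start, no internal stops, TAA stop; length n % 3 == 0."""
    assert n % 3 == 0 and n >= 9
    codons = ["ATG"]
    for _ in range(n // 3 - 2):
        while True:
            c = _random_seq(rng, 3)
            if c not in _STOPS:
                break
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _layout_region(
    rng: np.random.Generator, specs: list[GeneSpec], region_len: int, min_gap: int = 60
) -> list[int]:
    """Start offsets for genes placed left-to-right with random spacers."""
    total = sum(s.genomic_span for s in specs)
    slack = region_len - total - min_gap * (len(specs) + 1)
    if slack < 0:
        raise ValueError(
            f"genes ({total} bp) exceed region capacity ({region_len} bp)"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=len(specs) + 1))
    starts = []
    pos = 0
    for i, spec in enumerate(specs):
        pos += min_gap + int(cuts[i] if i == 0 else cuts[i] - cuts[i - 1])
        starts.append(pos)
        pos += spec.genomic_span
    return starts


def _place_gene(
    rng: np.random.Generator, spec: GeneSpec, start: int, seq: bytearray
) -> GeneModel:
    """Write the gene's bases into ``seq`` (genome-forward orientation) and
    return its model with genomic exon intervals in transcript order."""
    if spec.kind == "CDS":
        transcript = _random_cds(rng, sum(spec.exon_lengths))
    else:
        transcript = _random_seq(rng, sum(spec.exon_lengths))
    introns = [_random_seq(rng, n) for n in spec.intron_lengths]
    pieces = []
    t = 0
    for i, el in enumerate(spec.exon_lengths):
        pieces.append(transcript[t : t + el])
        t += el
        if i < len(introns):
            pieces.append(introns[i])
    genomic = "".join(pieces)
    if spec.strand == -1:
        genomic = reverse_complement(genomic)
    seq[start : start + len(genomic)] = genomic.encode()
    # genomic exon intervals, transcript order
    intervals = []
    pos = start
    bounds = []
    for i, el in enumerate(spec.exon_lengths):
        bounds.append((pos, pos + el))
        pos += el
        if i < len(spec.intron_lengths):
            pos += spec.intron_lengths[i]
    if spec.strand == 1:
        intervals = [(s, e, 1) for s, e in bounds]
    else:
        # the genomic block was reverse-complemented, so transcript exon i
        # occupies the mirrored window within [start, start+span)
        span = spec.genomic_span
        intervals = [
            (start + span - (e2 - start), start + span - (s2 - start), -1)
            for s2, e2 in bounds
        ]
    return _build_model(spec.name, spec.kind, intervals, False, 10**9)


def make_ancestor(
    config: AncestorConfig | None = None, seed: int = 0
) -> tuple[PlastomeRecord, SyntheticTruth]:
    """Build the annotated ancestral genome; deterministic per seed."""
    config = config or AncestorConfig()
    rng = _stream(seed, "ancestor")
    L = config.genome_len
    lsc0, irb0 = 0, config.lsc_len
    ssc0 = irb0 + config.ir_len
    ira0 = ssc0 + config.ssc_len
    seq = bytearray(_random_seq(rng, L).encode())

    by_region: dict[str, list[GeneSpec]] = {"LSC": [], "IR": [], "SSC": []}
    for spec in config.genes:
        by_region[spec.region].append(spec)

    models: list[GeneModel] = []
    rps12_lsc_exon: tuple[int, int] | None = None
    # reserve room in the LSC for the rps12 5' exon by treating it as a spec
    lsc_specs = list(by_region["LSC"])
    if config.include_rps12:
        lsc_specs.append(GeneSpec("rps12_5p", "CDS", "LSC", -1, (RPS12_EXONS[0],)))
    ir_specs = list(by_region["IR"])
    if config.include_rps12:
        ir_specs.append(
            GeneSpec(
                "rps12_3p", "CDS", "IR", 1,
                (RPS12_EXONS[1], RPS12_EXONS[2]), (RPS12_INTRON2,),
            )
        )

    placements: dict[str, tuple[GeneSpec, int]] = {}
    for region, specs, offset, rlen in (
        ("LSC", lsc_specs, lsc0, config.lsc_len),
        ("IR", ir_specs, irb0, config.ir_len),
        ("SSC", by_region["SSC"], ssc0, config.ssc_len),
    ):
        if not specs:
            continue
        starts = _layout_region(_stream(seed, f"layout:{region}"), specs, rlen)
        for spec, s in zip(specs, starts):
            placements[spec.name] = (spec, offset + s)

    rps12_parts: dict[str, GeneModel] = {}
    for name, (spec, start) in placements.items():
        model = _place_gene(_stream(seed, f"gene:{name}"), spec, start, seq)
        if name in ("rps12_5p", "rps12_3p"):
            rps12_parts[name] = model
        else:
            models.append(model)

    if config.include_rps12:
        # assemble the trans-spliced gene from its parts; the 5' exon is a
        # plain minus-strand exon in the LSC, exons II-III sit in the IR.
        # The CDS must still be stop-free: regenerate the 5' exon so that the
        # concatenated transcript is one valid CDS.
        part5, part3 = rps12_parts["rps12_5p"], rps12_parts["rps12_3p"]
        cds = _random_cds(_stream(seed, "gene:rps12cds"), sum(RPS12_EXONS))
        exon1 = cds[: RPS12_EXONS[0]]
        s5, e5, _ = part5.exons[0]
        seq[s5:e5] = reverse_complement(exon1).encode()
        t = RPS12_EXONS[0]
        for (s, e, strand), el in zip(part3.exons, RPS12_EXONS[1:]):
            seq[s:e] = cds[t : t + el].encode()
            t += el
        models.append(
            _build_model(
                "rps12", "CDS",
                [part5.exons[0], *part3.exons],
                True, 10**9,
            )
        )

    # the IRa is the exact reverse complement of the IRb
    irb_seq = bytes(seq[irb0:ssc0]).decode()
    seq[ira0 : ira0 + config.ir_len] = reverse_complement(irb_seq).encode()
    # pin the four flanking bases so the planted repeat is *maximal*: by
    # chance a flank pair can reverse-complement-match and extend it
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for inner, outer in ((ssc0, ira0 - 1), (irb0 - 1, 0)):
        if chr(seq[inner]) == comp[chr(seq[outer])]:
            for base in _BASES:
                if base != chr(seq[inner]) and base != comp[chr(seq[outer])]:
                    seq[inner] = ord(base)
                    break

    def mirror(iv: tuple[int, int, int]) -> tuple[int, int, int]:
        s, e, strand = iv
        return (ira0 + (ssc0 - e), ira0 + (ssc0 - s), -strand)

    ir_models = [
        m for m in models if all(irb0 <= s and e <= ssc0 for s, e, _ in m.exons)
    ]
    for m in ir_models:
        mirrored = [mirror(iv) for iv in m.exons]
        models.append(_build_model(m.name, m.kind, mirrored, False, 10**9))
    # second rps12 copy: shared 5' exon + mirrored IR exons
    rps12_model = next((m for m in models if m.name == "rps12"), None)
    if rps12_model is not None:
        mirrored = [mirror(iv) for iv in rps12_model.exons[1:]]
        models.append(
            _build_model("rps12", "CDS", [rps12_model.exons[0], *mirrored], True, 10**9)
        )

    record = PlastomeRecord(
        accession="SYN_ANC",
        organism="Synthetica ancestralis",
        sequence=bytes(seq).decode(),
        circular=True,
        features=_assign_copy_indices(models),
    )
    truth = SyntheticTruth(
        seed=seed,
        ancestor=record,
        region_coords={
            "LSC": (lsc0, irb0),
            "IRb": (irb0, ssc0),
            "SSC": (ssc0, ira0),
            "IRa": (ira0, L),
        },
        tree_newick="",
        genus_map={},
        outgroups=(),
    )
    return record, truth


# ---------------------------------------------------------------------------
# cohort evolution
# ---------------------------------------------------------------------------

#: genus-structured guide tree; ingroup depths give worst pairwise
#: divergences near 2%, the regime where whole-gene identities sit in the
#: high 90s and only large planted indels push a gene below 95%
DEFAULT_TREE = (
    "((((NSY:0.0015,NTA:0.0015):0.0012,(NTO:0.0022,NUN:0.0022):0.0012):0.0070,"
    "(((SBU:0.0018,STU:0.0018):0.0015,SLY:0.0028):0.0042,"
    "((CAN:0.0035,ABE:0.0032):0.0015,DST:0.0042):0.0022):0.0028):0.0300,"
    "OG1:0.0450,OG2:0.0500);"
)

DEFAULT_GENUS_MAP = {
    "NSY": "Nicotiana", "NTA": "Nicotiana", "NTO": "Nicotiana", "NUN": "Nicotiana",
    "SBU": "Solanum", "SLY": "Solanum", "STU": "Solanum",
    "CAN": "Capsicum", "ABE": "Atropa", "DST": "Datura",
    "OG1": "Daucus", "OG2": "Coffea",
}

DEFAULT_OUTGROUPS = ("OG1", "OG2")

_NICOTIANA = frozenset({"NSY", "NTA", "NTO", "NUN"})
_SOLANUM = frozenset({"SBU", "SLY", "STU"})


@dataclass(frozen=True)
class PlantedEvent:
    """Requested named event; position is chosen by the generator."""

    gene: str
    region: str  # exon | intron
    etype: str  # insertion | deletion
    length: int
    species: frozenset[str]
    in_frame: bool = False
    exon_index: int | None = None  # restrict to one exon (transcript order)


#: the cohort's fixed study conditions: named indels of realistic sizes
DEFAULT_PLANTED: tuple[PlantedEvent, ...] = (
    PlantedEvent("accD", "exon", "insertion", 24, _NICOTIANA | {"DST"}, in_frame=True),
    PlantedEvent("accD", "exon", "insertion", 9, _SOLANUM, in_frame=True),
    PlantedEvent("accD", "exon", "insertion", 141, frozenset({"CAN"}), in_frame=True),
    PlantedEvent("accD", "exon", "deletion", 6, frozenset({"DST"}), in_frame=True),
    PlantedEvent("trnL-UAA", "intron", "deletion", 102, _NICOTIANA),
    PlantedEvent("trnL-UAA", "intron", "deletion", 71, frozenset({"CAN"})),
    PlantedEvent("rps16", "intron", "insertion", 38, frozenset({"ABE"})),
    PlantedEvent("rps16", "intron", "insertion", 9, frozenset({"SLY"})),
    PlantedEvent("rps16", "exon", "deletion", 9, _NICOTIANA, in_frame=True, exon_index=1),
    PlantedEvent("clpP", "exon", "insertion", 30, frozenset({"SLY"}), in_frame=True, exon_index=2),
    PlantedEvent("clpP", "exon", "insertion", 6, frozenset({"SBU", "STU"}), in_frame=True, exon_index=2),
    PlantedEvent("clpP", "intron", "deletion", 13, frozenset({"CAN"})),
    PlantedEvent("ndhA", "intron", "deletion", 9, frozenset({"CAN"})),
    PlantedEvent("ndhA", "intron", "insertion", 5, frozenset({"SLY"})),
    PlantedEvent("ycf1", "exon", "insertion", 18, frozenset({"CAN"}), in_frame=True),
    PlantedEvent("ycf1", "exon", "deletion", 6, frozenset({"DST"}), in_frame=True),
    PlantedEvent("ycf1", "exon", "insertion", 6, _NICOTIANA, in_frame=True),
    PlantedEvent("ycf1", "exon", "deletion", 9, frozenset({"NTO"}), in_frame=True),
    PlantedEvent("rpl32", "exon", "insertion", 3, frozenset({"CAN"}), in_frame=True),
)


@dataclass(frozen=True)
class CohortConfig:
    tree_newick: str = DEFAULT_TREE
    genus_map: tuple[tuple[str, str], ...] = tuple(sorted(DEFAULT_GENUS_MAP.items()))
    outgroups: tuple[str, ...] = DEFAULT_OUTGROUPS
    sub_rate: float = 1.0  # multiplier on branch length = subs per site
    indel_rate: float = 0.04  # indel events per substitution
    in_frame_prob: float = 1.0  # background CDS-exon indels kept in frame
    max_indel_len: int = 12
    margin: int = 18  # events keep this far from segment boundaries
    separation: int = 30  # min gap between event windows
    planted: tuple[PlantedEvent, ...] = DEFAULT_PLANTED

    def genus_of(self) -> dict[str, str]:
        return dict(self.genus_map)


class _SegmentIndex:
    """Exon/intron/intergenic segmentation of the single-copy regions in
    ancestor coordinates, plus codon-frame helpers for CDS exons."""

    def __init__(self, record: PlastomeRecord, region_coords, margin: int):
        self.record = record
        self.margin = margin
        lsc = region_coords["LSC"]
        ssc = region_coords["SSC"]
        self.sc_ranges = [lsc, ssc]
        segs: list[tuple[str, str | None, int, int, GeneModel | None]] = []
        covered: list[tuple[int, int]] = []
        for m in record.features:
            if m.copy_index != 1:
                continue
            for s, e, _ in m.exons:
                if self._in_single_copy(s, e):
                    segs.append(("exon", m.name, s, e, m))
                    covered.append((s, e))
            for s, e in m.introns:
                if self._in_single_copy(s, e):
                    segs.append(("intron", m.name, s, e, m))
                    covered.append((s, e))
        covered.sort()
        for lo, hi in self.sc_ranges:
            pos = lo
            for s, e in covered:
                if e <= lo or s >= hi:
                    continue
                if s > pos:
                    segs.append(("intergenic", None, pos, s, None))
                pos = max(pos, e)
            if pos < hi:
                segs.append(("intergenic", None, pos, hi, None))
        self.segments = sorted(segs, key=lambda t: t[2])
        self.models = {m.name: m for m in record.features if m.copy_index == 1}

    def _in_single_copy(self, s: int, e: int) -> bool:
        return any(lo <= s and e <= hi for lo, hi in self.sc_ranges)

    def locate(self, pos: int) -> tuple[str, str | None]:
        for label, gene, s, e, _ in self.segments:
            if s <= pos < e:
                return label, gene
        return "intergenic", None

    def transcript_coord(self, model: GeneModel, pos: int) -> int | None:
        acc = 0
        for s, e, strand in model.exons:
            if s <= pos < e:
                return acc + (pos - s if strand == 1 else e - 1 - pos)
            acc += e - s
        return None


def _collect_branches(tree_newick: str):
    from .phylo import parse_newick

    root = parse_newick(tree_newick)
    branches = []

    def visit(node):
        leaves = frozenset(node.leaves())
        if node is not root:
            branches.append((",".join(sorted(leaves)), leaves, node.length))
        for c in node.children:
            visit(c)

    visit(root)
    species = sorted(root.leaves())
    return species, branches


class _WindowLedger:
    """Disjoint event windows kept at least ``separation`` bp apart (and the
    same margin around them is kept substitution-free) so that alignment gap
    placement stays unambiguous."""

    def __init__(self, separation: int):
        self.sep = separation
        self.windows: list[tuple[int, int]] = []

    def free(self, lo: int, hi: int) -> bool:
        return all(hi + self.sep <= a or b + self.sep <= lo for a, b in self.windows)

    def reserve(self, lo: int, hi: int) -> None:
        self.windows.append((lo, hi))

    def covers(self, pos: int) -> bool:
        return any(a - self.sep <= pos < b + self.sep for a, b in self.windows)


def _candidate_segments(index: _SegmentIndex, ev: PlantedEvent):
    out = []
    exon_counter: dict[str, int] = {}
    for label, gene, s, e, model in index.segments:
        if gene != ev.gene or label != ev.region:
            continue
        if ev.exon_index is not None and label == "exon":
            k = exon_counter.get(gene, 0)
            exon_counter[gene] = k + 1
            if k != ev.exon_index:
                continue
        out.append((s, e, model))
    return out


def _frame_aligned(index: _SegmentIndex, model: GeneModel, pos: int) -> bool:
    t = index.transcript_coord(model, pos)
    return t is not None and t % 3 == 0


def _insertion_payload(rng: np.random.Generator, length: int, in_frame_cds: bool) -> str:
    if not in_frame_cds:
        return _random_seq(rng, length)
    codons = []
    for _ in range(length // 3):
        while True:
            c = _random_seq(rng, 3)
            if c not in _STOPS:
                break
        codons.append(c)
    return "".join(codons)


def _place_event(
    rng: np.random.Generator,
    index: _SegmentIndex,
    ledger: _WindowLedger,
    ev: PlantedEvent,
    margin: int,
) -> SimEvent | None:
    candidates = _candidate_segments(index, ev)
    rng.shuffle(candidates)
    for s, e, model in candidates:
        lo, hi = s + margin, e - margin
        if ev.etype == "deletion":
            hi -= ev.length
        if hi <= lo:
            continue
        for _ in range(200):
            pos = int(rng.integers(lo, hi))
            if ev.in_frame and model is not None and model.kind == "CDS":
                t = index.transcript_coord(model, pos)
                if t is None:
                    continue
                shift = (3 - t % 3) % 3
                if model.exons[0][2] == -1:
                    # on the minus strand the transcript runs right-to-left;
                    # step back to the nearest codon boundary instead
                    pos -= shift
                else:
                    pos += shift
                if not (lo <= pos < hi):
                    continue
                if not _frame_aligned(index, model, pos) and ev.etype == "deletion":
                    continue
            wlo, whi = (pos, pos + ev.length) if ev.etype == "deletion" else (pos, pos)
            if not ledger.free(wlo, whi):
                continue
            if ev.etype == "deletion" and not (s + margin <= pos and pos + ev.length <= e - margin + 1):
                continue
            ledger.reserve(wlo, whi)
            in_frame_cds = ev.in_frame and model is not None and model.kind == "CDS"
            payload = None
            if ev.etype == "insertion":
                payload = _insertion_payload(rng, ev.length, in_frame_cds)
            return SimEvent(
                etype=ev.etype,
                species=ev.species,
                gene=ev.gene,
                region=ev.region,
                pos=pos,
                length=ev.length,
                payload=payload,
                source="planted",
            )
    return None


def _sample_background(
    seed: int,
    index: _SegmentIndex,
    ledger: _WindowLedger,
    config: CohortConfig,
    branches,
) -> list[SimEvent]:
    """Random per-branch substitutions and indels.

    Indels for every branch are placed first (each inside its own reserved
    window); substitutions are then sampled anywhere outside those windows.
    This ordering keeps the indel rate independent of the substitution rate
    while guaranteeing that no substitution sits next to a gap, which would
    make multiple-alignment gap placement ambiguous.
    """
    events: list[SimEvent] = []
    used_sub_positions: set[int] = set()
    # one substitution per CDS codon cohort-wide: two hits in one codon can
    # combine into a stop on a shared path even when each alone is silent
    used_codons: set[tuple[str, int]] = set()
    eligible = [
        (label, gene, s, e, model)
        for label, gene, s, e, model in index.segments
        if e - s > 2 * config.margin
    ]
    seg_weights = np.array([e - s for _, _, s, e, _ in eligible], dtype=float)
    seg_weights /= seg_weights.sum()
    total_sites = sum(e - s for _, _, s, e, _ in eligible)
    ancestor_seq = index.record.sequence

    expected: list[tuple[str, frozenset, int, int]] = []
    for node_id, leaves, blen in branches:
        rng = _stream(seed, f"counts:{node_id}")
        n_subs = rng.binomial(total_sites, min(1.0, blen * config.sub_rate))
        n_indels = rng.poisson(n_subs * config.indel_rate)
        expected.append((node_id, leaves, n_subs, n_indels))

    for node_id, leaves, _n_subs, n_indels in expected:
        rng = _stream(seed, f"indels:{node_id}")
        for _ in range(n_indels):
            etype = "deletion" if rng.random() < 0.5 else "insertion"
            length = int(rng.integers(1, config.max_indel_len + 1))
            for _try in range(100):
                k = rng.choice(len(eligible), p=seg_weights)
                label, gene, s, e, model = eligible[k]
                in_cds_exon = label == "exon" and model is not None and model.kind == "CDS"
                if in_cds_exon and model.exons[0][2] == -1:
                    # keeping minus-strand coding indels in frame would need
                    # orientation-specific payloads; coding indels are placed
                    # on plus-strand genes only
                    continue
                ln = length
                if in_cds_exon and rng.random() < config.in_frame_prob:
                    ln = max(3, (length // 3) * 3)
                pos = int(rng.integers(s + config.margin, max(s + config.margin + 1, e - config.margin - ln)))
                if in_cds_exon:
                    t = index.transcript_coord(model, pos)
                    if t is None:
                        continue
                    pos += (3 - t % 3) % 3
                if not (s + config.margin <= pos and pos + (ln if etype == "deletion" else 0) <= e - config.margin):
                    continue
                wlo, whi = (pos, pos + ln) if etype == "deletion" else (pos, pos)
                if not ledger.free(wlo, whi):
                    continue
                ledger.reserve(wlo, whi)
                payload = None
                if etype == "insertion":
                    payload = _insertion_payload(rng, ln, in_cds_exon)
                events.append(SimEvent(etype, leaves, gene, label, pos, ln, payload, node_id))
                break

    for node_id, leaves, n_subs, _n_indels in expected:
        rng = _stream(seed, f"subs:{node_id}")
        for _ in range(n_subs):
            for _try in range(50):
                k = rng.choice(len(eligible), p=seg_weights)
                label, gene, s, e, model = eligible[k]
                pos = int(rng.integers(s, e))
                if pos in used_sub_positions or ledger.covers(pos):
                    continue
                in_cds = label == "exon" and model is not None and model.kind == "CDS"
                codon_key = None
                if in_cds:
                    t = index.transcript_coord(model, pos)
                    codon_key = (model.name, t // 3)
                    if codon_key in used_codons:
                        continue
                    # never touch an existing stop (or start) codon: losing
                    # the terminal stop silently lengthens the protein
                    spliced = gene_sequence(index.record, model)
                    codon = spliced[(t // 3) * 3 : (t // 3) * 3 + 3]
                    if codon in _STOPS or t < 3:
                        continue
                old = ancestor_seq[pos]
                alternatives = [b for b in _BASES if b != old]
                rng.shuffle(alternatives)
                new = None
                for cand in alternatives:
                    if in_cds and _creates_stop(index, model, pos, cand):
                        continue
                    new = cand
                    break
                if new is None:
                    continue
                used_sub_positions.add(pos)
                if codon_key is not None:
                    used_codons.add(codon_key)
                events.append(
                    SimEvent("substitution", leaves, gene, label, pos, 1, new, node_id)
                )
                break
    return events


def _creates_stop(index: _SegmentIndex, model: GeneModel, pos: int, base: str) -> bool:
    t = index.transcript_coord(model, pos)
    if t is None:
        return False
    record = index.record
    spliced = gene_sequence(record, model)
    strand = None
    for s, e, st in model.exons:
        if s <= pos < e:
            strand = st
            break
    b = base if strand == 1 else reverse_complement(base)
    codon_start = (t // 3) * 3
    codon = list(spliced[codon_start : codon_start + 3])
    if len(codon) < 3:
        return False
    codon[t % 3] = b
    return "".join(codon) in _STOPS


def _lift_interval(s: int, e: int, indels: list[SimEvent]) -> tuple[int, int]:
    ds = de = 0
    for ev in indels:
        if ev.etype == "insertion":
            if ev.pos <= s:
                ds += ev.length
                de += ev.length
            elif ev.pos < e:
                de += ev.length
        else:
            if ev.pos + ev.length <= s:
                ds -= ev.length
                de -= ev.length
            elif s <= ev.pos and ev.pos + ev.length <= e:
                de -= ev.length
    return s + ds, e + de


def evolve_cohort(
    ancestor: PlastomeRecord,
    truth: SyntheticTruth,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[list[PlastomeRecord], SyntheticTruth]:
    """Evolve the cohort along the guide tree and complete the truth log.

    Every mutation is recorded in ancestor coordinates inside globally
    disjoint windows; the inverted repeat is left untouched.  Annotations
    are lifted over the per-species indels, so each emitted record carries
    valid gene models.
    """
    config = config or CohortConfig()
    species, branches = _collect_branches(config.tree_newick)
    index = _SegmentIndex(ancestor, truth.region_coords, config.margin)
    ledger = _WindowLedger(config.separation)

    events: list[SimEvent] = []
    rng_planted = _stream(seed, "planted")
    for i, pv in enumerate(config.planted):
        ev = _place_event(rng_planted, index, ledger, pv, config.margin)
        if ev is None:
            raise ValueError(f"could not place planted event {i}: {pv}")
        events.append(ev)
    events.extend(_sample_background(seed, index, ledger, config, branches))

    truth.tree_newick = config.tree_newick
    truth.genus_map = config.genus_of()
    truth.outgroups = tuple(config.outgroups)
    truth.species = species
    truth.events = events

    records = []
    for sp in species:
        seq = truth.replay(sp)
        indels = [
            e for e in events if sp in e.species and e.etype != "substitution"
        ]
        models = []
        for m in ancestor.features:
            lifted = [
                (*_lift_interval(s, e, indels), strand) for s, e, strand in m.exons
            ]
            models.append(_build_model(m.name, m.kind, lifted, m.trans_spliced, len(seq)))
        genus = truth.genus_map.get(sp, "Synthetica")
        records.append(
            PlastomeRecord(
                accession=f"SYN_{sp}",
                organism=f"{genus} {sp.lower()}",
                sequence=seq,
                circular=True,
                features=_assign_copy_indices(models),
            )
        )
    return records, truth


def default_cohort(
    seed: int = 0,
    ancestor_config: AncestorConfig | None = None,
    cohort_config: CohortConfig | None = None,
) -> tuple[PlastomeRecord, list[PlastomeRecord], SyntheticTruth]:
    """The standard fixture cohort: ancestor + 12 evolved species + truth."""
    ancestor, truth = make_ancestor(ancestor_config, seed=seed)
    records, truth = evolve_cohort(ancestor, truth, cohort_config, seed=seed)
    return ancestor, records, truth


def write_cohort(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialize the standard cohort: per-species GenBank files under
    ``genomes/`` (ready to feed to the pipeline), plus the ancestor record,
    a cohort FASTA and the machine-readable truth log."""
    directory = Path(directory)
    genome_dir = directory / "genomes"
    genome_dir.mkdir(parents=True, exist_ok=True)
    ancestor, records, truth = default_cohort(seed)
    paths: dict[str, Path] = {"genomes": genome_dir}
    for rec in records:
        write_genbank([rec], genome_dir / f"{rec.accession}.gb")
    anc = directory / "ancestor.gb"
    write_genbank([ancestor], anc)
    paths["ancestor"] = anc
    fasta = directory / "cohort.fasta"
    with open(fasta, "w") as fh:
        for rec in [ancestor, *records]:
            fh.write(f">{rec.accession} {rec.organism}\n{rec.sequence}\n")
    paths["fasta"] = fasta
    tj = directory / "truth.json"
    truth.to_json(tj)
    paths["truth"] = tj
    return paths
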