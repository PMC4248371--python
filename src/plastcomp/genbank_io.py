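"""Reading and writing annotated plastome records.

GenBank flat files are the external interchange format (1-based, inclusive
coordinates); everything inside the package works with 0-based half-open
intervals in genome orientation, converted only here.  Each annotated gene
copy becomes a :class:`GeneModel` whose exons are listed 5'->3' in
transcript orientation, with introns derived as the gaps between
consecutive exons of a cis-spliced transcript.  Trans-spliced genes (the
plastid rps12) keep their exon list but mark the junction(s) where no
genomic intron exists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FeatureLocation",
    "GeneModel",
    "PlastomeRecord",
    "GenBankParseError",
    "GeneModelError",
    "parse_genbank",
    "derive_gene_models",
    "write_genbank",
    "read_fasta",
    "gene_sequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: feature types that carry gene models
_FEATURE_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "ncRNA": "ncRNA"}

#: distance between consecutive exons above which a junction is treated as
#: trans-spliced even without an explicit /trans_splicing qualifier
_TRANS_GAP_BP = 20_000


class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be converted to a plastome model."""


class GeneModelError(ValueError):
    """Raised when a feature's exon structure is internally inconsistent."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureLocation:
    """Multi-interval feature location.

    ``intervals`` are (start, end, strand) triples, 0-based half-open in
    genome coordinates, listed 5'->3' in transcript orientation.  An
    interval of an origin-spanning feature is stored unwrapped, i.e. its
    ``end`` may exceed the genome length.
    """

    intervals: tuple[tuple[int, int, int], ...]
    spans_origin: bool = False

    def __post_init__(self) -> None:
        for start, end, strand in self.intervals:
            if start >= end:
                raise GeneModelError(f"empty interval {start}..{end}")
            if strand not in (1, -1):
                raise GeneModelError(f"bad strand {strand!r}")

    @property
    def span(self) -> int:
        return sum(end - start for start, end, _ in self.intervals)


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene copy with derived exon/intron structure.

    ``exons`` repeats the location intervals (transcript order); ``introns``
    holds the genomic gaps between consecutive cis-spliced exons, also in
    transcript order.  ``trans_junctions`` indexes the exon junctions
    (0 = between exon I and exon II) that are trans-spliced and therefore
    have no genomic intron.  IR-duplicated genes carry ``copy_index`` 1/2
    by genomic position of their first exon.
    """

    name: str
    kind: str
    location: FeatureLocation
    exons: tuple[tuple[int, int, int], ...]
    introns: tuple[tuple[int, int], ...]
    trans_spliced: bool = False
    trans_junctions: frozenset[int] = frozenset()
    copy_index: int = 1

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e, _ in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def intron_lengths(self) -> list[int | None]:
        """Length of the intron after each exon junction; None where the
        junction is trans-spliced (no genomic intron exists)."""
        out: list[int | None] = []
        cis = list(self.introns)
        k = 0
        for j in range(len(self.exons) - 1):
            if j in self.trans_junctions:
                out.append(None)
            else:
                s, e = cis[k]
                out.append(e - s)
                k += 1
        return out


@dataclass
class PlastomeRecord:
    """An annotated (usually circular) plastid genome."""

    accession: str
    organism: str
    sequence: str
    circular: bool = True
    features: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.accession:
            raise GenBankParseError("record has no accession")
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise GenBankParseError(f"{self.accession}: non-ACGTN letters {bad}")
        for model in self.features:
            _validate_model(model, self.length_bp)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Genome slice, 0-based half-open; ``end`` may wrap past the origin."""
        if end <= self.length_bp:
            return self.sequence[start:end]
        return (self.sequence + self.sequence)[start:end]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlastomeRecord):
            return NotImplemented
        return (
            self.accession == other.accession
            and self.organism == other.organism
            and self.sequence == other.sequence
            and self.circular == other.circular
            and self.features == other.features
        )


def _validate_model(model: GeneModel, length_bp: int) -> None:
    prev: list[tuple[int, int]] = []
    for start, end, _ in model.exons:
        if not (0 <= start < length_bp):
            raise GeneModelError(f"{model.name}: exon start {start} outside genome")
        if end - start < 1:
            raise GeneModelError(f"{model.name}: empty exon")
        if end > 2 * length_bp:
            raise GeneModelError(f"{model.name}: exon end {end} beyond one wrap")
        for ps, pe in prev:
            if start < pe and ps < end:
                raise GeneModelError(f"{model.name}: overlapping exons")
        prev.append((start, end))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_genbank(path: str | Path) -> list[PlastomeRecord]:
    """Parse a (possibly multi-record) GenBank flat file.

    Every gene-bearing feature (CDS/tRNA/rRNA/ncRNA) becomes one
    :class:`GeneModel`; features flagged ``/pseudo`` (or named with a
    pseudogene marker) get kind ``pseudogene``.  Origin-spanning locations
    are normalized to unwrapped intervals.
    """
    records = []
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:  # malformed location / file
        raise GenBankParseError(f"{path}: {exc}") from exc
    if not seq_records:
        raise GenBankParseError(f"{path}: no GenBank records found")
    for sr in seq_records:
        records.append(_from_seqrecord(sr))
    return records


def _from_seqrecord(sr: SeqRecord) -> PlastomeRecord:
    sequence = str(sr.seq).upper()
    topology = (sr.annotations.get("topology") or "").lower()
    record = PlastomeRecord(
        accession=sr.id or sr.name,
        organism=sr.annotations.get("organism", "") or "",
        sequence=sequence,
        circular=topology != "linear",
        features=[],
    )
    record.features = derive_gene_models_from_seqfeatures(sr.features, record.length_bp)
    return record


def _is_pseudo(feature: SeqFeature, name: str) -> bool:
    quals = feature.qualifiers
    if "pseudo" in quals or "pseudogene" in quals:
        return True
    return bool(re.search(r"(ψ|pseudo)", name, flags=re.IGNORECASE))


def _feature_name(feature: SeqFeature) -> str:
    for key in ("gene", "standard_name", "locus_tag", "product"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return ""


def derive_gene_models_from_seqfeatures(
    features: Sequence[SeqFeature], length_bp: int
) -> list[GeneModel]:
    models: list[GeneModel] = []
    for feature in features:
        if feature.type not in _FEATURE_KINDS:
            continue
        name = _feature_name(feature)
        if not name:
            raise GenBankParseError(f"feature {feature.type} at {feature.location} has no name")
        kind = "pseudogene" if _is_pseudo(feature, name) else _FEATURE_KINDS[feature.type]
        intervals = _normalize_parts(feature, length_bp)
        trans_flag = "trans_splicing" in feature.qualifiers
        models.append(_build_model(name, kind, intervals, trans_flag, length_bp))
    return _assign_copy_indices(models)


def _normalize_parts(feature: SeqFeature, length_bp: int) -> list[tuple[int, int, int]]:
    """Biopython parts (transcript order) -> unwrapped genome intervals."""
    parts = feature.location.parts
    raw = [(int(p.start), int(p.end), int(p.strand or 1)) for p in parts]
    # Detect an origin-spanning pair: consecutive plus-strand parts
    # ... x..L, 0..y  (or the mirror on the minus strand) belong to one exon.
    merged: list[tuple[int, int, int]] = []
    for start, end, strand in raw:
        if merged:
            ps, pe, pstrand = merged[-1]
            if strand == pstrand == 1 and pe == length_bp and start == 0:
                merged[-1] = (ps, length_bp + end, strand)
                continue
            if strand == pstrand == -1 and ps == 0 and end == length_bp:
                # minus strand wrap listed high-part-after-low in transcript order
                merged[-1] = (start, length_bp + pe, strand)
                continue
        merged.append((start, end, strand))
    return merged


def _build_model(
    name: str,
    kind: str,
    intervals: list[tuple[int, int, int]],
    trans_flag: bool,
    length_bp: int,
) -> GeneModel:
    introns: list[tuple[int, int]] = []
    trans_junctions: set[int] = set()
    for j in range(len(intervals) - 1):
        s1, e1, st1 = intervals[j]
        s2, e2, st2 = intervals[j + 1]
        if _is_trans_junction(intervals, j):
            trans_junctions.add(j)
        elif st1 == 1:
            introns.append((e1, s2))
        else:
            introns.append((e2, s1))
    trans = trans_flag or bool(trans_junctions)
    wraps = any(end > length_bp for _, end, _ in intervals)
    return GeneModel(
        name=name,
        kind=kind,
        location=FeatureLocation(tuple(intervals), spans_origin=wraps),
        exons=tuple(intervals),
        introns=tuple(introns),
        trans_spliced=trans,
        trans_junctions=frozenset(trans_junctions),
    )


def _is_trans_junction(intervals: list[tuple[int, int, int]], j: int) -> bool:
    """A junction is trans when strands differ or the genomic gap is huge."""
    s1, e1, st1 = intervals[j]
    s2, e2, st2 = intervals[j + 1]
    if st1 != st2:
        return True
    gap = (s2 - e1) if st1 == 1 else (s1 - e2)
    return gap < 0 or gap > _TRANS_GAP_BP


def _assign_copy_indices(models: list[GeneModel]) -> list[GeneModel]:
    seen: dict[tuple[str, str], int] = {}
    out = []
    order = sorted(range(len(models)), key=lambda i: min(s for s, _, _ in models[i].exons))
    copy_of = {}
    for i in order:
        key = (models[i].name.lower(), models[i].kind)
        seen[key] = seen.get(key, 0) + 1
        copy_of[i] = seen[key]
    for i, model in enumerate(models):
        out.append(replace(model, copy_index=copy_of[i]))
    return out


def derive_gene_models(record: PlastomeRecord) -> list[GeneModel]:
    """Return the record's gene models (already derived at parse time).

    Re-validates exon/intron consistency and copy indices so that records
    assembled programmatically go through the same checks as parsed ones.
    """
    for model in record.features:
        _validate_model(model, record.length_bp)
    return _assign_copy_indices(record.features)


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------


def _extract(sequence: str, start: int, end: int) -> str:
    L = len(sequence)
    if end <= L:
        return sequence[start:end]
    return sequence[start:] + sequence[: end - L]


def gene_sequence(
    record: PlastomeRecord, model: GeneModel, include_introns: bool = False
) -> str:
    """Gene sequence in transcript orientation (5'->3').

    With ``include_introns`` the full genomic span between the first and
    last exon of each cis block is used, which is the natural unit for
    whole-gene identity comparisons of intron-containing genes.
    """
    if not include_introns or not model.introns:
        pieces = []
        for start, end, strand in model.exons:
            chunk = _extract(record.sequence, start, end)
            pieces.append(chunk if strand == 1 else reverse_complement(chunk))
        return "".join(pieces)
    # stitch cis blocks: exons plus intervening introns
    pieces = []
    block: list[tuple[int, int, int]] = []
    for j, exon in enumerate(model.exons):
        block.append(exon)
        if j == len(model.exons) - 1 or j in model.trans_junctions:
            strand = block[0][2]
            lo = min(s for s, _, _ in block)
            hi = max(e for _, e, _ in block)
            chunk = _extract(record.sequence, lo, hi)
            pieces.append(chunk if strand == 1 else reverse_complement(chunk))
            block = []
    return "".join(pieces)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_genbank(records: Iterable[PlastomeRecord], path: str | Path) -> None:
    """Serialize records so that ``parse_genbank`` recovers them exactly
    (sequence, topology, gene models and the qualifiers the pipeline uses)."""
    seq_records = []
    for record in records:
        sr = SeqRecord(
            Seq(record.sequence),
            id=record.accession,
            name=record.accession.split(".")[0][:16],
            description=f"{record.organism} plastid genome".strip(),
        )
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular" if record.circular else "linear"
        sr.annotations["organism"] = record.organism
        sr.annotations["source"] = record.organism
        src = SeqFeature(
            SimpleLocation(0, record.length_bp, 1),
            type="source",
            qualifiers={"organism": [record.organism]},
        )
        sr.features.append(src)
        for model in record.features:
            sr.features.append(_to_seqfeature(model, record.length_bp))
        seq_records.append(sr)
    SeqIO.write(seq_records, str(path), "genbank")


def _to_seqfeature(model: GeneModel, length_bp: int) -> SeqFeature:
    locs = []
    for start, end, strand in model.exons:
        if end > length_bp:  # origin-spanning exon -> split back into two parts
            first = SimpleLocation(start, length_bp, strand)
            second = SimpleLocation(0, end - length_bp, strand)
            locs.extend([first, second] if strand == 1 else [second, first])
        else:
            locs.append(SimpleLocation(start, end, strand))
    location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    ftype = model.kind if model.kind != "pseudogene" else "CDS"
    qualifiers: dict[str, list[str]] = {"gene": [model.name]}
    if model.kind == "pseudogene":
        qualifiers["pseudo"] = [""]
    if model.trans_spliced:
        qualifiers["trans_splicing"] = [""]
    return SeqFeature(location, type=ftype, qualifiers=qualifiers)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader (sequences only, no gene models)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
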