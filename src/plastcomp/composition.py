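"""Genome composition statistics: AT content by category and region, and the
coding / intron / intergenic percentage breakdown.

Conventions (these reproduce the arithmetic of published plastome tables):

* "coding" is the merged union of the exon intervals of every non-pseudogene
  feature copy — CDS, tRNA, rRNA and ncRNA alike, with both IR copies
  counted — so that coding + introns + intergenic closes to 100%;
* intron bases already covered by an exon of another (or the duplicated)
  gene copy count as coding, not intron;
* AT of the "IR" region is computed on a single IR copy;
* AT% = 100·(A+T)/(A+C+G+T): N bases are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .genbank_io import GeneModel, PlastomeRecord, gene_sequence
from .structure import QuadripartitePartition

__all__ = [
    "CompositionReport",
    "at_content",
    "partition_fractions",
    "category_at_profile",
    "composition_table",
    "round2",
]


def round2(x: float) -> float:
    """Round to two decimals, half away from zero (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CompositionReport:
    accession: str
    at_overall: float
    at_coding: float
    at_noncoding: float
    at_trna: float | None
    at_rrna: float | None
    at_protein_genes: float | None
    at_lsc: float | None
    at_ssc: float | None
    at_ir: float | None
    pct_coding: float
    pct_introns: float
    pct_intergenic: float
    warnings: list[str] = field(default_factory=list)


def at_content(seq: str) -> float:
    """AT percentage of a nucleotide string; N excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * at / acgt


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _wrap_split(intervals, length_bp):
    """Reduce unwrapped circular intervals to in-range pieces."""
    out = []
    for s, e in intervals:
        s %= length_bp
        if s + (e - s) <= length_bp:
            out.append((s, s + (e - s)))
        else:
            span = e - s
            out.append((s, length_bp))
            out.append((0, span - (length_bp - s)))
    return out


def _covered(intervals) -> int:
    return sum(e - s for s, e in intervals)


def _coding_union(models: list[GeneModel], length_bp: int) -> list[tuple[int, int]]:
    exons = [
        (s, e)
        for m in models
        if m.kind != "pseudogene"
        for s, e, _ in m.exons
    ]
    return _merge(_wrap_split(exons, length_bp))


def _intron_union(models: list[GeneModel], length_bp: int) -> list[tuple[int, int]]:
    introns = [(s, e) for m in models if m.kind != "pseudogene" for s, e in m.introns]
    return _merge(_wrap_split(introns, length_bp))


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference of merged interval lists."""
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def partition_fractions(
    record: PlastomeRecord, models: list[GeneModel] | None = None
) -> tuple[float, float, float]:
    """(pct_coding, pct_introns, pct_intergenic) as percent of genome length.

    Coding is the union of all exon intervals over all gene copies; introns
    are intron bases not inside any exon union; the remainder is intergenic.
    """
    models = record.features if models is None else models
    L = record.length_bp
    coding = _coding_union(models, L)
    introns = _subtract(_intron_union(models, L), coding)
    n_coding = _covered(coding)
    n_intron = _covered(introns)
    pct_coding = 100.0 * n_coding / L
    pct_introns = 100.0 * n_intron / L
    return pct_coding, pct_introns, 100.0 - pct_coding - pct_introns


def _seq_of(record: PlastomeRecord, intervals) -> str:
    return "".join(record.sequence[s:e] for s, e in intervals)


def category_at_profile(
    record: PlastomeRecord,
    models: list[GeneModel] | None = None,
    partition: QuadripartitePartition | None = None,
    cds_only: bool = False,
) -> CompositionReport:
    """Full composition report for one record.

    ``cds_only`` restricts the "coding" category to protein-coding exons
    (a sensitivity switch; structural RNAs then count as non-coding).
    """
    models = record.features if models is None else models
    if cds_only:
        frac_models = [m for m in models if m.kind == "CDS"]
    else:
        frac_models = models
    L = record.length_bp
    warnings: list[str] = []
    coding_iv = _coding_union(frac_models, L)
    noncoding_iv = _subtract([(0, L)], coding_iv)
    pct_coding, pct_introns, pct_intergenic = partition_fractions(record, frac_models)

    def _at(intervals) -> float | None:
        seq = _seq_of(record, intervals)
        return at_content(seq) if seq else None

    trna_seq = "".join(
        gene_sequence(record, m) for m in models if m.kind == "tRNA"
    )
    rrna_seq = "".join(
        gene_sequence(record, m, include_introns=True) for m in models if m.kind == "rRNA"
    )
    protein_seq = "".join(
        gene_sequence(record, m) for m in models if m.kind == "CDS"
    )
    at_lsc = at_ssc = at_ir = None
    if partition is not None:
        at_lsc = at_content(record.slice(partition.lsc.start, partition.lsc.end))
        at_ssc = at_content(record.slice(partition.ssc.start, partition.ssc.end))
        at_ir = at_content(record.slice(partition.irb.start, partition.irb.end))
    else:
        warnings.append("no quadripartite partition: LSC/SSC/IR AT fields absent")
    return CompositionReport(
        accession=record.accession,
        at_overall=at_content(record.sequence),
        at_coding=_at(coding_iv) if coding_iv else 0.0,
        at_noncoding=_at(noncoding_iv) if noncoding_iv else 0.0,
        at_trna=at_content(trna_seq) if trna_seq else None,
        at_rrna=at_content(rrna_seq) if rrna_seq else None,
        at_protein_genes=at_content(protein_seq) if protein_seq else None,
        at_lsc=at_lsc,
        at_ssc=at_ssc,
        at_ir=at_ir,
        pct_coding=pct_coding,
        pct_introns=pct_introns,
        pct_intergenic=pct_intergenic,
        warnings=warnings,
    )


def composition_table(reports: list[CompositionReport]) -> "pandas.DataFrame":  # noqa: F821
    """One row per accession, percentages rounded to two decimals."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append(
            {
                "accession": r.accession,
                "pct_coding": round2(r.pct_coding),
                "pct_introns": round2(r.pct_introns),
                "pct_intergenic": round2(r.pct_intergenic),
                "at_overall": round2(r.at_overall),
                "at_coding": round2(r.at_coding),
                "at_noncoding": round2(r.at_noncoding),
                "at_trna": None if r.at_trna is None else round2(r.at_trna),
                "at_rrna": None if r.at_rrna is None else round2(r.at_rrna),
                "at_protein_genes": None
                if r.at_protein_genes is None
                else round2(r.at_protein_genes),
                "at_lsc": None if r.at_lsc is None else round2(r.at_lsc),
                "at_ssc": None if r.at_ssc is None else round2(r.at_ssc),
                "at_ir": None if r.at_ir is None else round2(r.at_ir),
            }
        )
    return pd.DataFrame(rows)
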