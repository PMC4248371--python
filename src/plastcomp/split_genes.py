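"""Exon/intron length tables for intron-containing ("split") genes.

One row set per split gene, with segments labelled Exon I, Intron I,
Exon II, ... in transcript (5'->3') order, one column per record.  The
trans-spliced junction of rps12 has no genomic intron and is reported as
absent.  Genes duplicated in the inverted repeat are reported once, from
the copy with the lower genomic coordinate, and any structural disagreement
between the two copies is attached as a warning instead of being silently
merged away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genbank_io import GeneModel, PlastomeRecord

__all__ = ["SplitGeneTable", "split_gene_report", "GROUP_I_INTRON_GENES"]

#: the plastome's only group I intron lives in trnL-UAA; every other plastid
#: intron is group II (metadata only — no splicing chemistry is computed)
GROUP_I_INTRON_GENES = frozenset({"trnl-uaa"})

_SEGMENT_NAMES = ["Exon I", "Intron I", "Exon II", "Intron II", "Exon III"]


@dataclass
class SplitGeneTable:
    """Long-format split-gene report with IR-copy consistency warnings."""

    table: pd.DataFrame  # index (gene, segment), columns = accessions
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out = out.astype(object).where(out.notna(), "—")
        out.to_csv(path, sep="\t")


def _segments(model: GeneModel) -> dict[str, int | None]:
    """Alternating exon/intron lengths in transcript order."""
    out: dict[str, int | None] = {}
    intron_lengths = model.intron_lengths()
    for i, (s, e, _) in enumerate(model.exons):
        out[_exon_label(i)] = e - s
        if i < len(model.exons) - 1:
            out[_intron_label(i)] = intron_lengths[i]
    return out


def _roman(i: int) -> str:
    return ["I", "II", "III", "IV", "V"][i]


def _exon_label(i: int) -> str:
    return f"Exon {_roman(i)}"


def _intron_label(i: int) -> str:
    return f"Intron {_roman(i)}"


def split_gene_report(records: list[PlastomeRecord]) -> SplitGeneTable:
    """Build the cross-species exon/intron length table.

    Trans-spliced genes count as split genes (their cis introns are real);
    the trans junction itself is reported as an absent intron.
    """
    warnings: list[str] = []
    per_gene: dict[str, dict[str, dict[str, int | None]]] = {}
    for record in records:
        chosen: dict[str, GeneModel] = {}
        extra: dict[str, list[GeneModel]] = {}
        for model in record.features:
            if model.kind == "pseudogene":
                continue
            if not model.introns and not model.trans_junctions:
                continue
            key = model.name
            if key not in chosen or _first_coord(model) < _first_coord(chosen[key]):
                if key in chosen:
                    extra.setdefault(key, []).append(chosen[key])
                chosen[key] = model
            else:
                extra.setdefault(key, []).append(model)
        for name, model in chosen.items():
            for other in extra.get(name, []):
                if _segments(other) != _segments(model):
                    warnings.append(
                        f"{record.accession}:{name} IR copies disagree in "
                        f"exon/intron structure; reporting the lower-coordinate copy"
                    )
            per_gene.setdefault(name, {})[record.accession] = _segments(model)
    accessions = [r.accession for r in records]
    index = []
    data = {acc: [] for acc in accessions}
    for gene in sorted(per_gene, key=str.lower):
        labels: list[str] = []
        for by_acc in per_gene[gene].values():
            for lab in by_acc:
                if lab not in labels:
                    labels.append(lab)
        labels.sort(key=_SEGMENT_NAMES.index)
        for lab in labels:
            index.append((gene, lab))
            for acc in accessions:
                seg = per_gene[gene].get(acc, {})
                data[acc].append(seg.get(lab))
    table = pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(index, names=["gene", "segment"]),
        dtype="Int64",
    )
    return SplitGeneTable(table=table, warnings=warnings)


def _first_coord(model: GeneModel) -> int:
    return min(s for s, _, _ in model.exons)
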