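"""InDel event extraction from multiple alignments, localization to gene
structure, and species/genus specificity calls.

An *event* is a maximal run of alignment columns in which at least one row
is gapped; within the run different rows may be gapped over different
sub-spans (nested or staggered gaps), which is why an event carries a
length *range*: ``max_len`` is the column span and ``min_len`` the smallest
per-row gap length among the gapped rows.  Events whose gapped rows all
cover the identical column span have ``min_len == max_len``.

Polarity is reported relative to the majority state: when most rows carry
residues, the gapped minority has a deletion; when most rows are gapped,
the residue-bearing minority has an insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from Bio.Seq import Seq

from .genbank_io import GeneModel
from .msa import Msa

__all__ = [
    "IndelEvent",
    "Specificity",
    "extract_indels",
    "localize_events",
    "classify_specificity",
    "translate_cds",
    "indel_table",
]

GAP = "-"

#: the plastid (bacterial) genetic code
PLASTID_CODON_TABLE = 11


@dataclass(frozen=True)
class Specificity:
    kind: str  # species_specific | genus_specific | shared
    members: frozenset[str]
    genus: str | None = None

    def label(self) -> str:
        if self.kind == "species_specific":
            return f"species-specific({next(iter(self.members))})"
        if self.kind == "genus_specific":
            return f"genus-specific({self.genus})"
        return f"shared({','.join(sorted(self.members))})"


@dataclass
class IndelEvent:
    gene: str | None
    col_span: tuple[int, int]  # 0-based half-open alignment columns
    state: dict[str, str]  # species -> "gap" | "residue"
    gap_lengths: dict[str, int]  # per gapped species, columns gapped in span
    min_len: int
    max_len: int
    polarity: str = "deletion"  # of the minority, relative to majority state
    location: str | None = None  # exon | intron | boundary | noncoding
    specificity: Specificity | None = None

    @property
    def length_label(self) -> str:
        if self.min_len == self.max_len:
            return str(self.max_len)
        return f"{self.min_len}-{self.max_len}"


def extract_indels(msa: Msa, gene: str | None = None) -> list[IndelEvent]:
    """All InDel events of an alignment, ordered by column.

    A maximal run of columns each containing at least one gap is one event;
    rows gapped anywhere within the run are that event's gap carriers.
    """
    gaps = msa.gap_matrix()  # rows x cols
    names = msa.names
    any_gap = gaps.any(axis=0)
    events: list[IndelEvent] = []
    j = 0
    ncol = msa.length
    while j < ncol:
        if not any_gap[j]:
            j += 1
            continue
        start = j
        while j < ncol and any_gap[j]:
            j += 1
        block = gaps[:, start:j]
        counts = block.sum(axis=1)
        gap_lengths = {
            names[i]: int(counts[i]) for i in range(len(names)) if counts[i] > 0
        }
        state = {
            names[i]: ("gap" if counts[i] > 0 else "residue") for i in range(len(names))
        }
        gapped = [n for n in names if state[n] == "gap"]
        max_len = j - start
        min_len = min(gap_lengths.values())
        polarity = "deletion" if len(gapped) <= len(names) - len(gapped) else "insertion"
        events.append(
            IndelEvent(
                gene=gene,
                col_span=(start, j),
                state=state,
                gap_lengths=gap_lengths,
                min_len=min_len,
                max_len=max_len,
                polarity=polarity,
            )
        )
    return events


def _column_to_ref(msa: Msa, reference: str) -> np.ndarray:
    """For each alignment column, the number of reference residues strictly
    before it (i.e. the 0-based reference coordinate the column maps to)."""
    row = msa.rows[reference]
    positions = np.zeros(len(row) + 1, dtype=np.int64)
    k = 0
    for j, c in enumerate(row):
        positions[j] = k
        if c != GAP:
            k += 1
    positions[len(row)] = k
    return positions


def _gene_segments(model: GeneModel) -> list[tuple[str, int, int]]:
    """(label, start, end) segmentation of the gene's transcript-local span:
    alternating exon/intron intervals in transcript order."""
    segments: list[tuple[str, int, int]] = []
    pos = 0
    intron_lengths = model.intron_lengths()
    for i, (s, e, _) in enumerate(model.exons):
        length = e - s
        segments.append(("exon", pos, pos + length))
        pos += length
        if i < len(model.exons) - 1:
            il = intron_lengths[i]
            if il is not None:
                segments.append(("intron", pos, pos + il))
                pos += il
    return segments


def localize_events(
    events: list[IndelEvent],
    gene_model: GeneModel,
    reference_species: str,
    msa: Msa,
) -> list[IndelEvent]:
    """Fill each event's ``location`` by mapping its column span onto the
    reference species' gene structure.

    The reference row of the alignment must be the gene's transcript-local
    sequence (exons + cis introns, 5'->3').  A span wholly inside one exon
    (intron) is labelled exon (intron); one that crosses a junction is
    ``boundary``; zero-width insertions at a junction are ``boundary`` too.
    """
    if reference_species not in msa.rows:
        raise KeyError(f"reference row {reference_species!r} absent from alignment")
    col_to_ref = _column_to_ref(msa, reference_species)
    segments = _gene_segments(gene_model)
    total = segments[-1][2] if segments else 0
    out = []
    for ev in events:
        lo = int(col_to_ref[ev.col_span[0]])
        hi = int(col_to_ref[ev.col_span[1]])
        if lo >= total and total > 0:
            label = "noncoding"
        elif lo == hi:  # insertion relative to the reference
            containing = [
                lab for lab, s, e in segments if s < lo < e
            ]
            label = containing[0] if containing else "boundary"
        else:
            covering = [
                lab for lab, s, e in segments if s <= lo and hi <= e
            ]
            label = covering[0] if covering else "boundary"
        out.append(replace(ev, location=label))
    return out


def classify_specificity(
    event: IndelEvent, genus_map: Mapping[str, str]
) -> IndelEvent:
    """Attach a specificity call based on the minority gap/residue pattern.

    The differing set is whichever of (gapped rows, residue rows) is the
    minority (ties count the gapped set as differing).  One member: species
    specific.  Exactly the members of one genus: genus specific.  Anything
    else: shared.
    """
    gapped = frozenset(n for n, s in event.state.items() if s == "gap")
    residue = frozenset(event.state) - gapped
    minority = gapped if len(gapped) <= len(residue) else residue
    if len(minority) == 1:
        spec = Specificity("species_specific", minority)
    else:
        genera = {genus_map.get(n, n) for n in minority}
        if len(genera) == 1:
            genus = next(iter(genera))
            full_genus = frozenset(
                n for n in event.state if genus_map.get(n, n) == genus
            )
            if minority == full_genus:
                spec = Specificity("genus_specific", minority, genus=genus)
            else:
                spec = Specificity("shared", minority)
        else:
            spec = Specificity("shared", minority)
    return replace(event, specificity=spec)


def translate_cds(cds: str) -> tuple[str, list[str]]:
    """Translate a CDS under the plastid/bacterial code (table 11).

    The terminal stop is dropped.  An internal stop truncates the
    translation there and is reported as a warning rather than an error
    (pseudogenes and recent frameshifts do occur in real annotations).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    warnings: list[str] = []
    protein = str(Seq(cds).translate(table=PLASTID_CODON_TABLE))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        pos = protein.index("*")
        warnings.append(f"internal stop codon at aa position {pos + 1}; truncated")
        protein = protein[:pos]
    return protein, warnings


def indel_table(events_by_gene: Mapping[str, list[IndelEvent]]) -> "pandas.DataFrame":  # noqa: F821
    """Tidy event catalogue (one row per event) mirroring the published
    InDel summary tables."""
    import pandas as pd

    columns = [
        "gene", "indel", "col_start", "col_end", "length", "location",
        "polarity", "specificity",
    ]
    rows = []
    for gene in sorted(events_by_gene, key=str.lower):
        for k, ev in enumerate(events_by_gene[gene], start=1):
            rows.append(
                {
                    "gene": gene,
                    "indel": k,
                    "col_start": ev.col_span[0] + 1,
                    "col_end": ev.col_span[1],
                    "length": ev.length_label,
                    "location": ev.location,
                    "polarity": ev.polarity,
                    "specificity": ev.specificity.label() if ev.specificity else None,
                }
            )
    return pd.DataFrame(rows, columns=columns)
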