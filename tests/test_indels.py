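"""InDel extraction, localization, specificity, translation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcomp.genbank_io import FeatureLocation, GeneModel
from plastcomp.indels import (
    classify_specificity,
    extract_indels,
    localize_events,
    translate_cds,
)
from plastcomp.msa import Msa


def _msa(rows: dict[str, str]) -> Msa:
    return Msa(names=list(rows), rows=rows)


def scanner_oracle(rows: dict[str, str]):
    """Independent per-column scan: contiguous runs of gap-containing
    columns, with per-row gap counts, as (span, gapped_rows, min, max)."""
    names = list(rows)
    ncol = len(next(iter(rows.values())))
    events = []
    j = 0
    while j < ncol:
        if not any(rows[n][j] == "-" for n in names):
            j += 1
            continue
        start = j
        while j < ncol and any(rows[n][j] == "-" for n in names):
            j += 1
        counts = {n: rows[n][start:j].count("-") for n in names}
        gapped = frozenset(n for n, c in counts.items() if c)
        events.append(
            ((start, j), gapped, min(c for c in counts.values() if c), j - start)
        )
    return events


def test_single_gap_single_species():
    msa = _msa({"a": "ACGTTT", "b": "AC---T", "c": "ACGTTT"})
    (event,) = extract_indels(msa)
    assert event.col_span == (2, 5)
    assert event.min_len == event.max_len == 3
    assert event.state == {"a": "residue", "b": "gap", "c": "residue"}
    assert event.polarity == "deletion"
    event = classify_specificity(event, {})
    assert event.specificity.kind == "species_specific"
    assert event.specificity.members == frozenset({"b"})


def test_gap_free_alignment_yields_no_events():
    assert extract_indels(_msa({"a": "ACGT", "b": "ACGA"})) == []


def test_staggered_gaps_grouped_with_length_range():
    """Nested gap runs in one gappy block become a single event whose
    min/max span the per-row gap lengths."""
    msa = _msa({"a": "AAATTTTTTCCC", "b": "AAA------CCC", "c": "AAATT----CCC"})
    (event,) = extract_indels(msa)
    assert event.col_span == (3, 9)
    assert event.min_len == 4 and event.max_len == 6
    assert event.length_label == "4-6"
    assert event.gap_lengths == {"b": 6, "c": 4}


@settings(max_examples=120, deadline=None, derandomize=True)
@given(st.data())
def test_extraction_matches_column_scanner(data):
    """Property: event spans, gapped sets and length ranges equal the
    brute-force per-column scanner on random alignments <= 50 columns."""
    n_rows = data.draw(st.integers(2, 6))
    n_cols = data.draw(st.integers(2, 50))
    rows = {}
    for i in range(n_rows):
        rows[f"r{i}"] = "".join(
            data.draw(st.sampled_from("ACGT-")) for _ in range(n_cols)
        )
    # repair all-gap columns (invalid alignments)
    cols = [list(c) for c in zip(*rows.values())]
    for c in cols:
        if all(x == "-" for x in c):
            c[0] = "A"
    names = list(rows)
    rows = {n: "".join(c[i] for c in cols) for i, n in enumerate(names)}
    msa = _msa(rows)
    got = [
        (e.col_span, frozenset(k for k, v in e.state.items() if v == "gap"),
         e.min_len, e.max_len)
        for e in extract_indels(msa)
    ]
    assert got == scanner_oracle(rows)


def _two_exon_model() -> GeneModel:
    # transcript-local layout: exon [0,100) + intron [100,180) + exon [180,260)
    intervals = ((0, 100, 1), (180, 260, 1))
    return GeneModel(
        "g", "CDS", FeatureLocation(intervals), intervals, ((100, 180),)
    )


def test_localization_exon_intron_boundary():
    model = _two_exon_model()
    ref = "A" * 260  # reference row: full transcript-local gene span
    other = list(ref)
    msa_rows = {
        "ref": ref,
        "e": ref[:50] + "---" + ref[53:],     # inside exon I
        "i": ref[:120] + "----" + ref[124:],  # inside intron
        "b": ref[:98] + "-----" + ref[103:],  # crosses the exon/intron junction
    }
    msa = _msa(msa_rows)
    events = extract_indels(msa)
    events = localize_events(events, model, "ref", msa)
    by_span = {e.col_span[0]: e.location for e in events}
    assert by_span[50] == "exon"
    assert by_span[120] == "intron"
    assert by_span[98] == "boundary"


def test_zero_width_insertion_localized_at_point():
    model = _two_exon_model()
    ref = "A" * 260
    rows = {
        "ref": ref[:50] + "---" + ref[50:],   # insertion in others at exon pos 50
        "x": ref[:50] + "TTT" + ref[50:],
        "y": ref[:50] + "TTT" + ref[50:],
    }
    msa = _msa(rows)
    events = localize_events(extract_indels(msa), model, "ref", msa)
    (event,) = events
    assert event.location == "exon"
    # an insertion exactly at the exon/intron junction is a boundary call
    rows2 = {
        "ref": ref[:100] + "--" + ref[100:],
        "x": ref[:100] + "GG" + ref[100:],
        "y": ref[:100] + "GG" + ref[100:],
    }
    msa2 = _msa(rows2)
    (event2,) = localize_events(extract_indels(msa2), model, "ref", msa2)
    assert event2.location == "boundary"


def test_missing_reference_row_raises():
    msa = _msa({"a": "AC-T", "b": "ACGT"})
    with pytest.raises(KeyError):
        localize_events(extract_indels(msa), _two_exon_model(), "zz", msa)


GENUS = {"n1": "Nico", "n2": "Nico", "n3": "Nico", "s1": "Sol", "s2": "Sol",
         "c1": "Cap"}


def _event(gapped: set[str]):
    rows = {n: ("A-A" if n in gapped else "AAA") for n in GENUS}
    (event,) = extract_indels(_msa(rows))
    return classify_specificity(event, GENUS)


def test_specificity_calls():
    assert _event({"c1"}).specificity.kind == "species_specific"
    genus_call = _event({"n1", "n2", "n3"}).specificity
    assert genus_call.kind == "genus_specific" and genus_call.genus == "Nico"
    partial = _event({"n1", "n2"}).specificity  # not the whole genus
    assert partial.kind == "shared"
    mixed = _event({"n1", "s1"}).specificity
    assert mixed.kind == "shared" and mixed.members == frozenset({"n1", "s1"})


def test_specificity_tie_counts_gapped_side():
    rows = {n: "A-A" for n in ("a", "b", "c")} | {n: "AAA" for n in ("d", "e", "f")}
    (event,) = extract_indels(_msa(rows))
    call = classify_specificity(event, {})
    assert call.specificity.members == frozenset({"a", "b", "c"})


def test_translate_plastid_code():
    assert translate_cds("ATGGCTTAA") == ("MA", [])
    # no terminal stop present: translate the full frame, no warning
    protein, warnings = translate_cds("ATGACGGAT")
    assert protein == "MTD" and not warnings


def test_translate_internal_stop_truncates_with_warning():
    protein, warnings = translate_cds("ATGTAAGCTTAA")
    assert protein == "M"
    assert warnings and "internal stop" in warnings[0]


def test_translate_length_error():
    with pytest.raises(ValueError, match="divisible by 3"):
        translate_cds("ATGGC")


def test_planted_coding_indels_obey_three_to_one_rule(cohort, cohort_msas, species_of):
    """For in-frame coding events the nucleotide length is three times the
    amino-acid length at the homologous position (141 nt -> 47 aa etc.)."""
    from plastcomp.alignment import protein_scoring
    from plastcomp.genbank_io import gene_sequence
    from plastcomp.msa import progressive_msa

    ancestor, records, truth = cohort
    prots = {}
    for record in records:
        model = next(m for m in record.features if m.name == "accD")
        protein, warnings = translate_cds(gene_sequence(record, model))
        assert not warnings
        prots[species_of(record)] = protein
    aa_msa = progressive_msa(prots, scoring=protein_scoring(), alphabet="amino-acid")
    aa_events = extract_indels(aa_msa, gene="accD")
    sig_key = lambda t: (t[0], sorted(t[1]))  # noqa: E731
    aa_sigs = sorted(
        (
            (e.max_len, frozenset(k for k, v in e.state.items() if v == "gap"))
            for e in aa_events
        ),
        key=sig_key,
    )
    nt_sigs = sorted(
        (
            (length // 3, gapped)
            for length, gapped, region in truth.indel_signatures("accD", set(prots))
            if region == "exon"
        ),
        key=sig_key,
    )
    assert aa_sigs == nt_sigs
    assert any(length == 47 for length, _ in aa_sigs)  # the 141 bp insertion
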