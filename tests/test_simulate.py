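"""Synthetic-plastome generator: determinism, truth replay, constraints."""

from __future__ import annotations

import pytest

from plastcomp.composition import partition_fractions
from plastcomp.genbank_io import gene_sequence
from plastcomp.indels import translate_cds
from plastcomp.simulate import (
    AncestorConfig,
    CohortConfig,
    GeneSpec,
    default_cohort,
    evolve_cohort,
    make_ancestor,
)
from plastcomp.structure import detect_inverted_repeat


def test_same_seed_identical_ancestor():
    a1, _ = make_ancestor(seed=5)
    a2, _ = make_ancestor(seed=5)
    assert a1 == a2
    a3, _ = make_ancestor(seed=6)
    assert a3.sequence != a1.sequence


def test_bare_quadripartite_config_detected_exactly():
    config = AncestorConfig(lsc_len=8000, ir_len=3000, ssc_len=2000,
                            genes=(), include_rps12=False)
    record, truth = make_ancestor(config, seed=2)
    assert record.length_bp == 16000
    part = detect_inverted_repeat(record, min_len=1000)
    assert part.irb.length == 3000
    assert (part.lsc.start, part.lsc.length) == (0, 8000)
    assert partition_fractions(record) == pytest.approx((0.0, 0.0, 100.0))


def test_infeasible_config_raises():
    config = AncestorConfig(
        lsc_len=2000, ir_len=3000, ssc_len=2000,
        genes=(GeneSpec("huge", "CDS", "LSC", 1, (3000,)),),
        include_rps12=False,
    )
    with pytest.raises(ValueError, match="capacity"):
        make_ancestor(config, seed=0)


def test_zero_rates_yield_identical_species():
    ancestor, truth = make_ancestor(seed=3)
    config = CohortConfig(sub_rate=0.0, indel_rate=0.0, planted=())
    records, truth = evolve_cohort(ancestor, truth, config, seed=3)
    assert len(records) == 12
    for record in records:
        assert record.sequence == ancestor.sequence
        assert [m.exons for m in record.features] == [m.exons for m in ancestor.features]


def test_truth_replay_reproduces_every_species(cohort, species_of):
    _, records, truth = cohort
    for record in records:
        assert truth.replay(species_of(record)) == record.sequence


def test_event_windows_disjoint_and_separated(cohort):
    _, _, truth = cohort
    windows = sorted(
        e.window() for e in truth.events if e.etype != "substitution"
    )
    for (lo1, hi1), (lo2, hi2) in zip(windows, windows[1:]):
        assert hi1 < lo2  # disjoint
    # substitutions stay clear of indel windows
    sep = CohortConfig().separation
    subs = [e.pos for e in truth.events if e.etype == "substitution"]
    for pos in subs:
        for lo, hi in windows:
            assert not (lo - sep <= pos < hi + sep)


def test_event_regions_consistent_with_ancestor_models(cohort):
    ancestor, _, truth = cohort
    exon, intron = set(), set()
    for model in ancestor.features:
        for s, e, _ in model.exons:
            exon.update(range(s, e))
        for s, e in model.introns:
            intron.update(range(s, e))
    for ev in truth.events:
        span = range(ev.pos, ev.pos + (ev.length if ev.etype == "deletion" else 1))
        if ev.region == "exon":
            assert set(span) <= exon
        elif ev.region == "intron":
            assert set(span) <= intron and not (set(span) & exon)
        else:
            assert not (set(span) & (exon | intron))


def test_planted_events_present_with_requested_sizes(cohort):
    _, _, truth = cohort
    planted = [e for e in truth.events if e.source == "planted"]
    key = {(e.gene, e.etype, e.length, e.species) for e in planted}
    nicotiana = frozenset({"NSY", "NTA", "NTO", "NUN"})
    assert ("accD", "insertion", 141, frozenset({"CAN"})) in key
    assert ("trnL-UAA", "deletion", 102, nicotiana) in key
    assert ("accD", "insertion", 24, nicotiana | {"DST"}) in key
    assert ("rps16", "insertion", 38, frozenset({"ABE"})) in key


def test_coding_indels_in_frame_and_cds_translatable(cohort, species_of):
    _, records, truth = cohort
    for ev in truth.events:
        if ev.etype != "substitution" and ev.region == "exon":
            # all default-config coding indels are in frame
            assert ev.length % 3 == 0
    for record in records:
        for model in record.features:
            if model.kind == "CDS" and model.copy_index == 1:
                cds = gene_sequence(record, model)
                assert len(cds) % 3 == 0
                _, warnings = translate_cds(cds)
                assert not warnings, (record.accession, model.name)


def test_no_deletion_removes_an_entire_exon(cohort):
    ancestor, _, truth = cohort
    exons = [
        (s, e) for m in ancestor.features for s, e, _ in m.exons
    ]
    for ev in truth.events:
        if ev.etype != "deletion":
            continue
        for s, e in exons:
            assert not (ev.pos <= s and e <= ev.pos + ev.length)


def test_cohort_determinism(cohort):
    ancestor, records, truth = cohort
    anc2, records2, truth2 = default_cohort(seed=1)
    assert ancestor == anc2
    assert records == records2
    assert [
        (e.etype, e.pos, e.length, e.payload, sorted(e.species)) for e in truth.events
    ] == [
        (e.etype, e.pos, e.length, e.payload, sorted(e.species)) for e in truth2.events
    ]


def test_truth_json_serializes(tmp_path, cohort):
    _, _, truth = cohort
    out = tmp_path / "truth.json"
    truth.to_json(out)
    import json

    payload = json.loads(out.read_text())
    assert payload["species"] == truth.species
    assert len(payload["events"]) == len(truth.events)
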