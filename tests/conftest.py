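"""Shared fixtures: the standard synthetic cohort and derived objects.

Everything expensive (cohort generation, per-gene alignments) is computed
once per session; individual tests treat these as read-only.
"""

from __future__ import annotations

import pytest

from plastcomp.genbank_io import gene_sequence
from plastcomp.msa import progressive_msa
from plastcomp.simulate import default_cohort

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort():
    """(ancestor, records, truth) for the standard 12-species cohort."""
    return default_cohort(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def species_of():
    return lambda record: record.accession.split("_")[1]


@pytest.fixture(scope="session")
def cohort_gene_seqs(cohort, species_of):
    """gene -> {species code -> full gene span sequence} over all 12 species."""
    _, records, _ = cohort
    genes: dict[str, dict[str, str]] = {}
    for record in records:
        for model in record.features:
            if model.copy_index != 1 or model.kind == "pseudogene":
                continue
            genes.setdefault(model.name, {})[species_of(record)] = gene_sequence(
                record, model, include_introns=True
            )
    return genes


@pytest.fixture(scope="session")
def cohort_msas(cohort_gene_seqs):
    """gene -> Msa across the full cohort (None where all rows identical)."""
    out = {}
    for gene, seqs in cohort_gene_seqs.items():
        out[gene] = None if len(set(seqs.values())) == 1 else progressive_msa(seqs)
    return out
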