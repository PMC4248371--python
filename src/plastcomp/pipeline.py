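"""End-to-end comparative-plastome pipeline over a directory of GenBank
files.

Produces the four report families — structure/composition, split genes,
identity/divergence, InDel catalogues (nucleotide and protein) — plus a
bootstrap phylogeny and a JSON manifest (config hash, versions, seed,
per-stage timings and warnings).  Per-record parse failures are isolated:
the pipeline continues with the remaining records and reports the failure
in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

from . import __version__
from .alignment import (
    NUCLEOTIDE_SCORING,
    Scoring,
    classify_divergence,
    identity_matrix,
    protein_scoring,
)
from .composition import category_at_profile, composition_table
from .genbank_io import PlastomeRecord, gene_sequence, parse_genbank
from .indels import (
    classify_specificity,
    extract_indels,
    indel_table,
    localize_events,
    translate_cds,
)
from .msa import Msa, progressive_msa, write_fasta_msa
from .phylo import bootstrap_support, build_supermatrix, to_newick
from .split_genes import split_gene_report
from .structure import detect_inverted_repeat, partition_table

__all__ = ["DEFAULT_CONFIG", "load_config", "run_all", "gene_sets_of"]

DEFAULT_CONFIG: dict = {
    # structure
    "ir_min_len": 1000,
    "ir_max_mismatch": 0,
    # identity / divergence
    "divergent_below": 95.0,
    "conserved_at": 100.0,
    "genes_with_introns": True,  # compare full gene spans (exons + introns)
    "identity_max_missing": 3,
    # alignment scoring (nucleotide)
    "match": NUCLEOTIDE_SCORING.match,
    "mismatch": NUCLEOTIDE_SCORING.mismatch,
    "gap_open": NUCLEOTIDE_SCORING.gap_open,
    "gap_extend": NUCLEOTIDE_SCORING.gap_extend,
    # phylogeny
    "bootstrap_replicates": 500,
    "distance_model": "jc",
    "phylo_exclude": ["accD", "rpl20", "ycf1", "ycf15"],
    "phylo_genes": None,  # None = all protein-coding genes minus exclusions
    "outgroups": [],  # organism or accession substrings marking outgroups
    # indel catalogue
    "indel_genes": None,  # None = the divergent set
}

_STAGES = ("structure", "composition", "splitgenes", "identity", "indels", "phylo")


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML/JSON config file over the defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(DEFAULT_CONFIG)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        config.update(loaded)
    return config


def _scoring_from(config: dict) -> Scoring:
    return Scoring(
        match=float(config["match"]),
        mismatch=float(config["mismatch"]),
        gap_open=float(config["gap_open"]),
        gap_extend=float(config["gap_extend"]),
    )


def _species_label(record: PlastomeRecord) -> str:
    return record.accession

def _genus_of(record: PlastomeRecord) -> str:
    return record.organism.split()[0] if record.organism else record.accession


def _is_outgroup(record: PlastomeRecord, config: dict) -> bool:
    tokens = config.get("outgroups") or []
    return any(
        t.lower() in record.accession.lower() or t.lower() in record.organism.lower()
        for t in tokens
    )


def gene_sets_of(
    records: list[PlastomeRecord], include_introns: bool = True
) -> dict[str, dict[str, str]]:
    """species label -> {gene name -> sequence (transcript orientation)};
    first gene copy only, pseudogenes excluded."""
    out: dict[str, dict[str, str]] = {}
    for record in records:
        genes: dict[str, str] = {}
        for model in record.features:
            if model.kind == "pseudogene" or model.copy_index != 1:
                continue
            genes[model.name] = gene_sequence(record, model, include_introns=include_introns)
        out[_species_label(record)] = genes
    return out


def _load_records(input_dir: Path, manifest: dict) -> list[PlastomeRecord]:
    records: list[PlastomeRecord] = []
    files = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in (".gb", ".gbk", ".genbank")
    )
    for path in files:
        try:
            records.extend(parse_genbank(path))
        except Exception as exc:  # noqa: BLE001 - per-record isolation is the contract
            manifest["errors"].append({"file": path.name, "error": str(exc)})
    return records


def run_all(
    input_dir: str | Path,
    output_dir: str | Path,
    config: dict | None = None,
    seed: int = 0,
    stages: tuple[str, ...] = _STAGES,
) -> dict:
    """Run the requested stages and write the report bundle.

    Returns the manifest (also written as ``manifest.json``).
    """
    t_start = time.time()
    config = dict(DEFAULT_CONFIG, **(config or {}))
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "stages": list(stages),
        "inputs": {},
        "outputs": [],
        "timings_s": {},
        "warnings": [],
        "errors": [],
    }
    records = _load_records(input_dir, manifest)
    if len(records) < 2:
        raise ValueError(f"{input_dir}: need at least two parseable records")
    for path in sorted(input_dir.iterdir()):
        if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
            manifest["inputs"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    ingroup = [r for r in records if not _is_outgroup(r, config)]
    scoring = _scoring_from(config)
    genus_map = {_species_label(r): _genus_of(r) for r in records}

    def _emit(name: str, writer) -> None:
        path = output_dir / name
        writer(path)
        manifest["outputs"].append(name)

    partitions = {}
    if "structure" in stages or "composition" in stages:
        t0 = time.time()
        for record in records:
            partitions[record.accession] = detect_inverted_repeat(
                record,
                min_len=int(config["ir_min_len"]),
                max_mismatch=int(config["ir_max_mismatch"]),
            )
        if "structure" in stages:
            table = partition_table([(r, partitions[r.accession]) for r in records])
            _emit("structure.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
        manifest["timings_s"]["structure"] = round(time.time() - t0, 3)

    if "composition" in stages:
        t0 = time.time()
        reports = []
        for record in records:
            rep = category_at_profile(record, partition=partitions.get(record.accession))
            manifest["warnings"].extend(f"{record.accession}: {w}" for w in rep.warnings)
            reports.append(rep)
        table = composition_table(reports)
        _emit("composition.tsv", lambda p: table.to_csv(p, sep="\t", index=False))
        manifest["timings_s"]["composition"] = round(time.time() - t0, 3)

    if "splitgenes" in stages:
        t0 = time.time()
        report = split_gene_report(records)
        manifest["warnings"].extend(report.warnings)
        _emit("split_genes.tsv", report.to_tsv)
        manifest["timings_s"]["splitgenes"] = round(time.time() - t0, 3)

    divergent: list[str] = []
    gene_sets = gene_sets_of(ingroup, include_introns=bool(config["genes_with_introns"]))
    if "identity" in stages or "indels" in stages:
        t0 = time.time()
        matrix = identity_matrix(
            gene_sets, scoring=scoring, max_missing=int(config["identity_max_missing"])
        )
        calls, pair_counts = classify_divergence(
            matrix,
            divergent_below=float(config["divergent_below"]),
            conserved_at=float(config["conserved_at"]),
        )
        divergent = sorted(
            (g for g, c in calls.items() if c.klass == "highly_divergent"), key=str.lower
        )
        if "identity" in stages:
            _emit("identity_matrix.tsv", lambda p: matrix.to_csv(p, sep="\t"))
            payload = {
                "divergent_genes": divergent,
                "conserved_gene_counts_per_pair": pair_counts,
                "dropped_genes": matrix.attrs.get("dropped_genes", []),
                "calls": {
                    g: {
                        "class": c.klass,
                        "min_identity": round(c.min_identity, 2),
                        "conserved_pairs": c.conserved_pairs,
                        "bins": c.bins,
                    }
                    for g, c in calls.items()
                },
            }
            _emit(
                "divergence.json",
                lambda p: Path(p).write_text(json.dumps(payload, indent=1)),
            )
        manifest["timings_s"]["identity"] = round(time.time() - t0, 3)

    if "indels" in stages:
        t0 = time.time()
        targets = config["indel_genes"] or divergent
        nt_events: dict[str, list] = {}
        aa_events: dict[str, list] = {}
        for gene in targets:
            seqs = {
                sp: genes[gene] for sp, genes in gene_sets.items() if gene in genes
            }
            if len(seqs) < 2 or len(set(seqs.values())) == 1:
                nt_events[gene] = []
                continue
            msa = progressive_msa(seqs, scoring=scoring)
            write_fasta_msa(msa, output_dir / f"msa_{gene}.fasta")
            manifest["outputs"].append(f"msa_{gene}.fasta")
            events = extract_indels(msa, gene=gene)
            reference = sorted(seqs)[0]
            model = _gene_model(ingroup, reference, gene)
            if model is not None:
                events = localize_events(events, model, reference, msa)
            events = [classify_specificity(ev, genus_map) for ev in events]
            nt_events[gene] = events
            aa = _protein_events(ingroup, gene, genus_map, manifest)
            if aa is not None:
                aa_events[gene] = aa
        _emit("indels_nt.tsv", lambda p: indel_table(nt_events).to_csv(p, sep="\t", index=False))
        _emit("indels_aa.tsv", lambda p: indel_table(aa_events).to_csv(p, sep="\t", index=False))
        manifest["timings_s"]["indels"] = round(time.time() - t0, 3)

    if "phylo" in stages:
        t0 = time.time()
        msas: dict[str, Msa] = {}
        all_sets = gene_sets_of(records, include_introns=False)
        cds_genes = sorted(
            {
                m.name
                for r in records
                for m in r.features
                if m.kind == "CDS" and m.copy_index == 1
            },
            key=str.lower,
        )
        wanted = config["phylo_genes"] or cds_genes
        for gene in wanted:
            seqs = {sp: genes[gene] for sp, genes in all_sets.items() if gene in genes}
            if len(seqs) < 2:
                continue
            if len(set(seqs.values())) == 1:
                width = len(next(iter(seqs.values())))
                msas[gene] = Msa(names=sorted(seqs), rows=dict(seqs))
            else:
                msas[gene] = progressive_msa(seqs, scoring=scoring)
        sm = build_supermatrix(msas, exclude=tuple(config["phylo_exclude"]))
        tree, skipped = bootstrap_support(
            sm,
            replicates=int(config["bootstrap_replicates"]),
            seed=seed,
            model=str(config["distance_model"]),
        )
        if skipped:
            manifest["warnings"].append(f"phylo: {skipped} bootstrap replicates skipped")
        _emit("supermatrix.fasta", lambda p: _write_supermatrix(sm, p))
        _emit("tree.nwk", lambda p: Path(p).write_text(to_newick(tree, with_support=True) + "\n"))
        manifest["timings_s"]["phylo"] = round(time.time() - t0, 3)

    manifest["timings_s"]["total"] = round(time.time() - t_start, 3)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _gene_model(records: list[PlastomeRecord], label: str, gene: str):
    for record in records:
        if _species_label(record) == label:
            for model in record.features:
                if model.name == gene and model.copy_index == 1:
                    return model
    return None


def _protein_events(records, gene, genus_map, manifest):
    """Independent protein-level InDel catalogue for a CDS gene."""
    prots = {}
    for record in records:
        model = next(
            (m for m in record.features if m.name == gene and m.copy_index == 1), None
        )
        if model is None or model.kind != "CDS":
            return None
        cds = gene_sequence(record, model)
        if len(cds) % 3:
            manifest["warnings"].append(
                f"{record.accession}:{gene}: CDS length not divisible by 3; "
                "protein catalogue skipped"
            )
            return None
        prot, warns = translate_cds(cds)
        manifest["warnings"].extend(f"{record.accession}:{gene}: {w}" for w in warns)
        prots[_species_label(record)] = prot
    if len(set(prots.values())) == 1:
        return []
    msa = progressive_msa(prots, scoring=protein_scoring(), alphabet="amino-acid")
    events = extract_indels(msa, gene=gene)
    return [classify_specificity(ev, genus_map) for ev in events]


def _write_supermatrix(sm, path) -> None:
    with open(path, "w") as fh:
        for taxon in sm.taxa:
            fh.write(f">{taxon}\n{sm.rows[taxon]}\n")
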