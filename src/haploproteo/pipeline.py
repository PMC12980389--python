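"""End-to-end orchestration of the bespoke stages.

Ties variant processing, haplotype projection, database assembly and
post-search annotation together behind one configuration object. External
tools (aligner, caller, phaser, search engine) are not invoked; their
standard-format outputs are the inputs here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO

from . import database, postsearch, variants as vp
from .model import (
    Thresholds,
    TranscriptModel,
    Variant,
    read_genome,
    read_phased_variants,
    read_transcripts,
    spliced_cds_sequence,
    write_vcf,
)
from .projection import (
    HaplotypeProtein,
    assign_haplotype_labels,
    project_transcript_haplotypes,
    translate_cds,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str
    gtf: str
    vcf: str
    out_dir: str
    reference_proteome: Optional[str] = None
    contaminants: Optional[str] = None
    psms: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("genome", "gtf", "vcf", "reference_proteome",
                     "contaminants", "psms"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{name} path does not exist: {path}")


def standardize_transcripts(txs: list[TranscriptModel],
                            th: Thresholds) -> list[TranscriptModel]:
    """Keep transcripts with a complete CDS: length a multiple of 3 and at
    least the minimum CDS length."""
    return [tx for tx in txs
            if tx.cds_length % 3 == 0 and tx.cds_length >= th.min_cds_nt]


def reference_proteome(genome: dict[str, str], txs: list[TranscriptModel]
                       ) -> list[tuple[str, str]]:
    """Translate each transcript CDS into its reference protein."""
    out = []
    for tx in sorted(txs, key=lambda t: t.transcript_id):
        aa, _stop, _idx = translate_cds(spliced_cds_sequence(genome, tx))
        out.append((tx.transcript_id, aa))
    return out


def project_all(genome: dict[str, str], txs: list[TranscriptModel],
                variants: list[Variant], th: Thresholds
                ) -> list[HaplotypeProtein]:
    """Project every transcript and reconcile A/B labels per gene.

    Only variant-bearing products are returned; transcripts whose products
    equal the reference contribute nothing to the database replacement.
    """
    entries: list[HaplotypeProtein] = []
    for tx in sorted(txs, key=lambda t: t.transcript_id):
        products = project_transcript_haplotypes(genome, tx, variants, th)
        if any(hp.applied_variants for hp in products):
            entries.extend(products)
    assign_haplotype_labels(entries)
    return entries


def _read_fasta_pairs(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """variant processing -> projection -> database; then annotation if a
    PSM table is supplied. Returns the manifest (also written to disk)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    th = config.thresholds
    outputs: list[str] = []

    def out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        outputs.append(path)
        return path

    genome = read_genome(config.genome)
    txs = standardize_transcripts(read_transcripts(config.gtf), th)
    raw_variants = read_phased_variants(config.vcf)
    kept, report = vp.process_variants(raw_variants, txs, th)
    write_vcf(kept, out("variants.processed.vcf"),
              contigs={c: len(s) for c, s in genome.items()})
    with open(out("filter_report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    projections = project_all(genome, txs, kept, th)
    reference = (_read_fasta_pairs(config.reference_proteome)
                 if config.reference_proteome
                 else reference_proteome(genome, txs))
    contaminants = (_read_fasta_pairs(config.contaminants)
                    if config.contaminants else [])
    entries = database.build_database(
        reference, projections, contaminants=contaminants, th=th,
        seed=config.seed)
    database.write_database(entries, out("database.fasta"), out("database.tsv"))

    annotation = postsearch.build_annotation_records(projections)
    annotation.to_csv(out("protein_annotation.tsv"), sep="\t", index=False)

    if config.psms:
        db = postsearch.DatabaseIndex(
            entries, projections,
            reference_proteome=[seq for _, seq in reference])
        psms = postsearch.read_psm_table(config.psms)
        accepted = postsearch.filter_psms(psms, db, th)
        pep_ann = postsearch.annotate_peptides(accepted, db)
        import pandas as pd
        pd.DataFrame([{
            "peptide": a.peptide, "category": a.category,
            "haplotype": a.haplotype_call,
            "covered_variants": ";".join(
                f"{tid}:{v}" for tid, v in a.covered_variants),
        } for a in pep_ann]).to_csv(out("peptides.tsv"), sep="\t", index=False)

        groups = postsearch.infer_protein_groups(accepted, db)
        pd.DataFrame([{
            "group_id": g.group_id,
            "members": ";".join(g.member_entry_ids),
            "n_peptides": len(g.supporting_peptides),
        } for g in groups]).to_csv(out("protein_groups.tsv"), sep="\t",
                                   index=False)

        genes = postsearch.identify_genes(
            groups, postsearch.build_gene_map(db, txs))
        with open(out("genes.txt"), "w") as fh:
            fh.write("\n".join(sorted(genes)) + ("\n" if genes else ""))

        direct = postsearch.identify_direct_variants(accepted, db)
        linked = postsearch.infer_linked_variants(direct, projections)
        pd.DataFrame([{
            "chrom": vi.variant.chrom, "pos": vi.variant.pos,
            "ref": vi.variant.ref_allele, "alt": vi.variant.alt_allele,
            "transcript_id": vi.transcript_id, "mode": vi.mode,
            "zygosity": vi.zygosity,
        } for vi in direct + linked]).to_csv(
            out("variant_identifications.tsv"), sep="\t", index=False)

        tx_by_id = {tx.transcript_id: tx for tx in txs}
        bed_rows = []
        for hp in projections:
            eid = hp.entry_id
            entry = next((e for e in entries if eid in e.member_ids
                          and not e.is_decoy), None)
            if entry is None:
                continue
            tx = tx_by_id[hp.transcript_id]
            for pep in sorted(accepted):
                if pep in entry.aa_sequence:
                    ivs = postsearch.project_peptide_to_genome(
                        pep, entry, tx, hp)
                    bed_rows.append((tx.chrom, ivs, f"{pep}|{eid}", tx.strand))
        postsearch.write_bed12(bed_rows, out("peptides.bed"))

    manifest = {
        "config": {
            **{k: getattr(config, k) for k in (
                "genome", "gtf", "vcf", "reference_proteome", "contaminants",
                "psms", "out_dir", "seed")},
            "thresholds": dataclasses.asdict(th),
        },
        "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
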