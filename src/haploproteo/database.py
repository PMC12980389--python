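"""Sample-specific search database assembly.

Merges the reference proteome with haplotype and novel-splice products,
deduplicates sequences while tracking contributing accessions, appends
contaminants, and generates reversed-sequence decoys whose tryptic peptides
are shuffled out of collision with the target peptide universe.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from pyteomics import parser as pt_parser

from .model import Thresholds, write_protein_fasta
from .projection import HaplotypeProtein

log = logging.getLogger(__name__)

DECOY_PREFIX = "XXX_"

# Cleave C-terminal of K/R unless followed by P.
TRYPSIN_RULE = r"[KR](?!P)"

CLASS_PRIORITY = ("reference", "variant", "novel_splice", "contaminant", "decoy")


@dataclass
class ProteinDatabaseEntry:
    entry_id: str
    aa_sequence: str
    member_ids: list[str] = field(default_factory=list)
    entry_class: str = "reference"

    def __post_init__(self) -> None:
        if not self.member_ids:
            self.member_ids = [self.entry_id]
        if self.entry_class not in CLASS_PRIORITY:
            raise ValueError(f"unknown entry class {self.entry_class!r}")

    @property
    def is_decoy(self) -> bool:
        return self.entry_class == "decoy"


def tryptic_digest(aa_sequence: str, max_missed: int = 2,
                   min_len: int = 5, max_len: int = 100) -> set[str]:
    """Tryptic peptides (cleave after K/R not before P) with missed cleavages.

    Returns the set of fragments carrying 0..max_missed internal cleavage
    sites, length-filtered to [min_len, max_len].
    """
    if not aa_sequence:
        raise ValueError("cannot digest an empty sequence")
    peps = pt_parser.cleave(aa_sequence, TRYPSIN_RULE,
                            missed_cleavages=max_missed, min_length=min_len or 1)
    return {p for p in peps if min_len <= len(p) <= max_len}


def assemble_sample_proteome(reference: list[tuple[str, str]],
                             haplotype_proteins: list[HaplotypeProtein],
                             novel_proteins: list[HaplotypeProtein] | None = None,
                             ) -> list[ProteinDatabaseEntry]:
    """Replace variant-bearing reference isoforms by their haplotype products.

    ``reference`` is (transcript accession, protein sequence) pairs. Every
    transcript with at least one non-silent applied variant is replaced by
    its haplotype entries (class ``variant``); novel-splice products are
    appended with class ``novel_splice`` whether or not they carry variants.
    """
    novel_proteins = novel_proteins or []
    ref_ids = {acc for acc, _ in reference}
    by_tx: dict[str, list[HaplotypeProtein]] = {}
    for hp in haplotype_proteins:
        if hp.transcript_id not in ref_ids:
            raise ValueError(
                f"haplotype protein references unknown transcript {hp.transcript_id}")
        by_tx.setdefault(hp.transcript_id, []).append(hp)
    replaced = {tid for tid, hps in by_tx.items()
                if any(hp.applied_variants for hp in hps)}
    out = []
    for acc, seq in reference:
        if acc in replaced:
            for hp in sorted(by_tx[acc], key=lambda h: h.entry_id):
                out.append(ProteinDatabaseEntry(
                    entry_id=hp.entry_id, aa_sequence=hp.aa_sequence,
                    entry_class="variant"))
        else:
            out.append(ProteinDatabaseEntry(entry_id=acc, aa_sequence=seq,
                                            entry_class="reference"))
    for hp in sorted(novel_proteins, key=lambda h: h.entry_id):
        out.append(ProteinDatabaseEntry(
            entry_id=hp.entry_id, aa_sequence=hp.aa_sequence,
            entry_class="novel_splice"))
    return out


def deduplicate_sequences(entries: list[ProteinDatabaseEntry]
                          ) -> list[ProteinDatabaseEntry]:
    """One entry per distinct sequence, tracking all contributing accessions.

    The surviving entry takes the lexicographically smallest member id; on a
    class conflict the highest-priority class wins (reference > variant >
    novel_splice > contaminant).
    """
    by_seq: dict[str, list[ProteinDatabaseEntry]] = {}
    for e in entries:
        by_seq.setdefault(e.aa_sequence, []).append(e)
    out = []
    for seq, group in by_seq.items():
        members = sorted({m for e in group for m in e.member_ids})
        cls = min((e.entry_class for e in group), key=CLASS_PRIORITY.index)
        out.append(ProteinDatabaseEntry(
            entry_id=members[0], aa_sequence=seq,
            member_ids=members, entry_class=cls))
    out.sort(key=lambda e: e.entry_id)
    return out


def generate_decoys(targets: list[ProteinDatabaseEntry], th: Thresholds,
                    seed: int) -> list[ProteinDatabaseEntry]:
    """One reversed-sequence decoy per target, collision-resolved by shuffling.

    Decoy tryptic peptides already present in the target peptide universe
    are shuffled in place (seeded RNG) for up to ``th.max_decoy_iterations``
    rounds; entries still colliding afterwards are emitted with a logged
    residual count, never dropped silently.
    """
    if any(t.is_decoy for t in targets):
        raise ValueError("targets already contain decoy entries")
    rng = random.Random(seed)
    digest = lambda s: tryptic_digest(
        s, th.max_missed_cleavages, th.min_peptide_len, th.max_peptide_len)
    universe: set[str] = set()
    for t in targets:
        universe |= digest(t.aa_sequence)
    decoys = []
    n_residual = 0
    for t in targets:
        seq = t.aa_sequence[::-1]
        for _ in range(th.max_decoy_iterations):
            colliding = digest(seq) & universe
            if not colliding:
                break
            chars = list(seq)
            for pep in sorted(colliding):
                start = seq.find(pep)
                while start != -1:
                    segment = chars[start:start + len(pep)]
                    rng.shuffle(segment)
                    chars[start:start + len(pep)] = segment
                    start = seq.find(pep, start + 1)
            seq = "".join(chars)
        residual = digest(seq) & universe
        if residual:
            n_residual += 1
            log.warning("decoy for %s keeps %d colliding peptides after %d "
                        "iterations", t.entry_id, len(residual),
                        th.max_decoy_iterations)
        decoys.append(ProteinDatabaseEntry(
            entry_id=DECOY_PREFIX + t.entry_id, aa_sequence=seq,
            member_ids=[DECOY_PREFIX + m for m in t.member_ids],
            entry_class="decoy"))
    if n_residual:
        log.warning("%d/%d decoys retain target-colliding peptides",
                    n_residual, len(targets))
    return decoys


def build_database(reference: list[tuple[str, str]],
                   haplotype_proteins: list[HaplotypeProtein],
                   novel_proteins: list[HaplotypeProtein] | None = None,
                   contaminants: list[tuple[str, str]] | None = None,
                   th: Thresholds = Thresholds(), seed: int = 0,
                   ) -> list[ProteinDatabaseEntry]:
    """Full assembly: merge, deduplicate, add contaminants, generate decoys."""
    entries = assemble_sample_proteome(reference, haplotype_proteins, novel_proteins)
    entries = deduplicate_sequences(entries)
    for acc, seq in contaminants or []:
        entries.append(ProteinDatabaseEntry(
            entry_id=acc, aa_sequence=seq, entry_class="contaminant"))
    return entries + generate_decoys(entries, th, seed)


def write_database(entries: list[ProteinDatabaseEntry], fasta_path: str,
                   sidecar_path: str) -> None:
    """Write the search FASTA plus the sidecar TSV (id, class, members)."""
    write_protein_fasta(((e.entry_id, e.aa_sequence) for e in entries), fasta_path)
    with open(sidecar_path, "w") as fh:
        fh.write("entry_id\tentry_class\tmember_ids\n")
        for e in entries:
            fh.write(f"{e.entry_id}\t{e.entry_class}\t{';'.join(e.member_ids)}\n")


def read_database(fasta_path: str, sidecar_path: str) -> list[ProteinDatabaseEntry]:
    from Bio import SeqIO
    meta = {}
    with open(sidecar_path) as fh:
        header = fh.readline()
        for line in fh:
            eid, cls, members = line.rstrip("\n").split("\t")
            meta[eid] = (cls, members.split(";"))
    out = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        cls, members = meta[rec.id]
        out.append(ProteinDatabaseEntry(
            entry_id=rec.id, aa_sequence=str(rec.seq),
            member_ids=members, entry_class=cls))
    return out
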