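"""Post-search annotation of peptide-spectrum matches.

Consumes an FDR-controlled PSM table plus the search database and the
haplotype projections behind it: classifies peptides (reference / variant /
splice), assigns peptide haplotypes, identifies variants directly (unique
spanning peptide) and by phase linkage, infers protein groups by greedy set
cover, applies the gene-level identification rule, and projects peptides
back to genome coordinates for browser tracks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .database import ProteinDatabaseEntry
from .model import Thresholds, TranscriptModel, Variant, cds_interval_to_genomic
from .projection import AppliedVariant, HaplotypeProtein, _edited_spans

log = logging.getLogger(__name__)

_MOD_RE = re.compile(r"\[[^\]]*\]|\([^)]*\)|[^A-Z]")


def strip_modifications(peptide: str) -> str:
    """Remove modification annotations, keeping the plain residue string."""
    return _MOD_RE.sub("", peptide)


@dataclass
class PeptideSpectrumMatch:
    peptide: str
    q_value: float
    matched_entry_ids: list[str]

    def __post_init__(self) -> None:
        self.peptide = strip_modifications(self.peptide)
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q-value {self.q_value} outside [0,1]")


@dataclass
class PeptideAnnotation:
    peptide: str
    category: str  # reference | variant | splice | variant_splice
    haplotype_call: str  # A | B | homozygous
    covered_variants: list[tuple[str, Variant]] = field(default_factory=list)


@dataclass
class ProteinGroup:
    member_entry_ids: list[str]
    supporting_peptides: set[str] = field(default_factory=set)

    @property
    def group_id(self) -> str:
        return self.member_entry_ids[0]


@dataclass
class VariantIdentification:
    variant: Variant
    transcript_id: str
    mode: str  # direct | linked
    zygosity: str  # homozygous | heterozygous


class DatabaseIndex:
    """Search database plus the projections behind its variant entries.

    Supports substring lookup of peptides against entries and exposes the
    applied variants (with protein coordinates) of each entry through its
    deduplication members.
    """

    def __init__(self, entries: list[ProteinDatabaseEntry],
                 projections: Iterable[HaplotypeProtein] = (),
                 reference_proteome: Optional[Iterable[str]] = None):
        self.entries: dict[str, ProteinDatabaseEntry] = {
            e.entry_id: e for e in entries}
        self.projections: dict[str, HaplotypeProtein] = {
            hp.entry_id: hp for hp in projections}
        # classification compares against the reference proteome, which
        # includes isoforms replaced by haplotype products in the database
        self.reference_sequences = (
            list(reference_proteome) if reference_proteome is not None
            else [e.aa_sequence for e in entries
                  if e.entry_class == "reference"])
        self._cache: dict[str, list[ProteinDatabaseEntry]] = {}

    def entry(self, entry_id: str) -> ProteinDatabaseEntry:
        try:
            return self.entries[entry_id]
        except KeyError:
            raise ValueError(f"unresolvable entry id {entry_id!r}") from None

    def entries_containing(self, peptide: str, include_decoys: bool = False
                           ) -> list[ProteinDatabaseEntry]:
        hits = self._cache.get(peptide)
        if hits is None:
            hits = [e for e in self.entries.values()
                    if not e.is_decoy and peptide in e.aa_sequence]
            self._cache[peptide] = hits
        if include_decoys:
            return hits + [e for e in self.entries.values()
                           if e.is_decoy and peptide in e.aa_sequence]
        return hits

    def applied_variants_of(self, entry: ProteinDatabaseEntry
                            ) -> list[tuple[HaplotypeProtein, AppliedVariant]]:
        out = []
        for member in entry.member_ids:
            hp = self.projections.get(member)
            if hp is not None:
                out.extend((hp, av) for av in hp.applied_variants)
        return out

    def variant_keys_of(self, entry: ProteinDatabaseEntry) -> set[tuple]:
        return {av.variant.key for _, av in self.applied_variants_of(entry)}

    def haplotype_call_of(self, entry: ProteinDatabaseEntry) -> Optional[str]:
        """A/B if the entry is a single-haplotype product, else None."""
        labels = set()
        for member in entry.member_ids:
            hp = self.projections.get(member)
            labels.add(hp.haplotype_label if hp is not None else "HOM")
        if len(labels) == 1 and labels <= {"A", "B"}:
            return labels.pop()
        return None


def read_psm_table(path: str) -> list[PeptideSpectrumMatch]:
    """Read the minimal PSM TSV: peptide, q_value, proteins (';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "proteins": str})
    return [PeptideSpectrumMatch(row.peptide, float(row.q_value),
                                 row.proteins.split(";"))
            for row in df.itertuples()]


def filter_psms(psms: list[PeptideSpectrumMatch], db: DatabaseIndex,
                th: Thresholds) -> set[str]:
    """Accepted peptides: q < threshold with >= 1 target (non-decoy,
    non-contaminant) match."""
    accepted = set()
    for psm in psms:
        entries = [db.entry(eid) for eid in psm.matched_entry_ids]
        if psm.q_value >= th.psm_q_max:
            continue
        if any(e.entry_class not in ("decoy", "contaminant") for e in entries):
            accepted.add(psm.peptide)
    return accepted


def classify_peptide(peptide: str, db: DatabaseIndex) -> str:
    """Categorize an accepted peptide by the entries that explain it.

    Reference takes precedence: any substring of a reference-class sequence
    is a reference peptide. Otherwise the explaining entry classes decide:
    only variant entries -> variant; only variant-free novel-splice entries
    -> splice; explanations involving variant-carrying novel-splice entries
    (or a mix of variant and splice entries) -> variant_splice.
    """
    if any(peptide in seq for seq in db.reference_sequences):
        return "reference"
    explaining = [e for e in db.entries_containing(peptide)
                  if e.entry_class in ("variant", "novel_splice")]
    if not explaining:
        raise ValueError(f"peptide {peptide!r} matches no target entry")
    classes = {e.entry_class for e in explaining}
    if classes == {"variant"}:
        return "variant"
    if classes == {"novel_splice"}:
        if all(db.variant_keys_of(e) for e in explaining):
            return "variant_splice"
        return "splice"
    return "variant_splice"


def assign_peptide_haplotype(peptide: str, db: DatabaseIndex) -> str:
    """A or B only when the peptide matches exactly one single-haplotype
    product; homozygous in every other case."""
    matches = db.entries_containing(peptide)
    if len(matches) == 1:
        call = db.haplotype_call_of(matches[0])
        if call is not None:
            return call
    return "homozygous"


def _peptide_covers(peptide: str, sequence: str, span: tuple[int, int]) -> bool:
    """Does any occurrence of peptide in sequence cover the residue span?"""
    s, e = span
    start = sequence.find(peptide)
    while start != -1:
        if start + 1 <= s and start + len(peptide) >= e:
            return True
        start = sequence.find(peptide, start + 1)
    return False


def _required_span(av: AppliedVariant, protein_len: int) -> tuple[int, int]:
    s, e = av.protein_start, av.protein_end
    if av.variant.variant_type == "indel":
        # full altered span plus one flanking residue each side (clamped)
        return max(1, s - 1), min(protein_len, e + 1)
    return s, e


def identify_direct_variants(accepted: set[str], db: DatabaseIndex
                             ) -> list[VariantIdentification]:
    """Variants confirmed by a unique peptide spanning the altered residues.

    A variant is direct when an accepted peptide occurs in an entry carrying
    the variant, covers its full altered span (indels: plus one flanking
    residue each side), and occurs in no entry lacking the variant.
    """
    out: dict[tuple, VariantIdentification] = {}
    for eid in sorted(db.entries.keys()):
        entry = db.entries[eid]
        if entry.is_decoy:
            continue
        for hp, av in db.applied_variants_of(entry):
            key = av.variant.key
            if key in out or av.protein_start is None:
                continue
            span = _required_span(av, len(entry.aa_sequence))
            for pep in sorted(accepted):
                if not _peptide_covers(pep, entry.aa_sequence, span):
                    continue
                elsewhere = [e for e in db.entries_containing(pep)
                             if e.entry_id != entry.entry_id
                             and key not in db.variant_keys_of(e)]
                if elsewhere:
                    continue
                out[key] = VariantIdentification(
                    variant=av.variant, transcript_id=hp.transcript_id,
                    mode="direct", zygosity=av.variant.zygosity)
                break
    return sorted(out.values(), key=lambda vi: vi.variant.key)


def infer_linked_variants(direct: list[VariantIdentification],
                          projections: Iterable[HaplotypeProtein],
                          ) -> list[VariantIdentification]:
    """Variants inferred through phase linkage with direct identifications.

    Heterozygous: shares a phase block (chrom, phase set) with a directly
    identified het. Homozygous: resides on a haplotype protein that carries
    at least one direct variant. Output is disjoint from the direct set.
    """
    projections = list(projections)
    direct_keys = {vi.variant.key for vi in direct}
    direct_het_blocks = {(vi.variant.chrom, vi.variant.phase_set)
                         for vi in direct
                         if vi.zygosity == "heterozygous"
                         and vi.variant.phase_set is not None}
    out: dict[tuple, VariantIdentification] = {}
    for hp in sorted(projections, key=lambda h: h.entry_id):
        entry_direct = any(av.variant.key in direct_keys
                           for av in hp.applied_variants)
        for av in hp.applied_variants:
            v = av.variant
            if v.key in direct_keys or v.key in out:
                continue
            if v.is_het:
                if (v.chrom, v.phase_set) in direct_het_blocks:
                    out[v.key] = VariantIdentification(
                        v, hp.transcript_id, "linked", "heterozygous")
            elif entry_direct:
                out[v.key] = VariantIdentification(
                    v, hp.transcript_id, "linked", "homozygous")
    return sorted(out.values(), key=lambda vi: vi.variant.key)


def infer_protein_groups(accepted: set[str], db: DatabaseIndex
                         ) -> list[ProteinGroup]:
    """Greedy set-cover protein inference.

    Entries with identical accepted-peptide sets merge into one candidate
    group; the greedy loop repeatedly picks the group covering the most
    still-uncovered peptides (ties broken by smallest member id) until the
    accepted peptide set is covered.
    """
    pepsets: dict[str, set[str]] = {}
    for eid, entry in db.entries.items():
        if entry.entry_class in ("decoy", "contaminant"):
            continue
        hits = {p for p in accepted if p in entry.aa_sequence}
        if hits:
            pepsets[eid] = hits
    merged: dict[frozenset, list[str]] = {}
    for eid, peps in pepsets.items():
        merged.setdefault(frozenset(peps), []).append(eid)
    candidates = [ProteinGroup(member_entry_ids=sorted(members),
                               supporting_peptides=set(peps))
                  for peps, members in merged.items()]
    covered: set[str] = set()
    target = set().union(*pepsets.values()) if pepsets else set()
    chosen: list[ProteinGroup] = []
    remaining = list(candidates)
    while covered != target:
        best = min(remaining,
                   key=lambda g: (-len(g.supporting_peptides - covered),
                                  g.group_id))
        gain = len(best.supporting_peptides - covered)
        if gain == 0:  # defensive; target is covered by construction
            break
        chosen.append(best)
        covered |= best.supporting_peptides
        remaining.remove(best)
    return chosen


def identify_genes(groups: list[ProteinGroup],
                   gene_map: dict[str, set[str]]) -> set[str]:
    """Genes with >= 1 protein group whose members all belong to that gene."""
    out = set()
    for g in groups:
        genes: set[str] = set()
        for eid in g.member_entry_ids:
            genes |= set(gene_map.get(eid) or {None})
        if len(genes) == 1 and None not in genes:
            out |= genes
    return out


def build_gene_map(db: DatabaseIndex, txs: list[TranscriptModel]
                   ) -> dict[str, set[str]]:
    """entry_id -> gene ids of all member accessions (haplotype suffixes
    ignored)."""
    tx_gene = {tx.transcript_id: tx.gene_id for tx in txs}
    out: dict[str, set[str]] = {}
    for eid, entry in db.entries.items():
        if entry.is_decoy:
            continue
        genes = set()
        for member in entry.member_ids:
            tid = re.sub(r"\.(A|B)$", "", member)
            if tid in tx_gene:
                genes.add(tx_gene[tid])
        out[eid] = genes
    return out


def annotate_peptides(accepted: set[str], db: DatabaseIndex
                      ) -> list[PeptideAnnotation]:
    out = []
    for pep in sorted(accepted):
        category = classify_peptide(pep, db)
        covered = []
        if category != "reference":
            for e in db.entries_containing(pep):
                for hp, av in db.applied_variants_of(e):
                    if av.protein_start is None:
                        continue
                    if _peptide_covers(pep, e.aa_sequence,
                                       (av.protein_start, av.protein_end)):
                        covered.append((hp.transcript_id, av.variant))
        out.append(PeptideAnnotation(
            peptide=pep, category=category,
            haplotype_call=assign_peptide_haplotype(pep, db),
            covered_variants=covered))
    return out


# ---------------------------------------------------------------------------
# Genome back-projection (browser tracks)
# ---------------------------------------------------------------------------

def _edited_to_ref_cds(pos: int, spans: list) -> int:
    """Map an edited-CDS nt position back to reference CDS coordinates.

    Positions inside an edited segment clamp to the segment's reference
    span; insertions therefore project onto their anchor bases.
    """
    offset = 0
    for av, s, e in spans:
        if pos < s:
            break
        if pos <= e:
            return min(av.cds_end, av.cds_pos + (pos - s))
        offset += av.delta
    return pos - offset


def project_peptide_to_genome(peptide: str, entry: ProteinDatabaseEntry,
                              tx: TranscriptModel, hp: HaplotypeProtein
                              ) -> list[tuple[int, int]]:
    """Genomic intervals (1-based inclusive) covered by a peptide.

    The peptide's residue span on the (variant-edited) protein is converted
    to edited-CDS nucleotides, mapped back to reference CDS coordinates by
    inverting the applied indel offsets, and projected through the exon
    structure; junction-spanning peptides yield multiple intervals.
    """
    offset = entry.aa_sequence.find(peptide)
    if offset == -1:
        raise ValueError(f"peptide {peptide!r} not found in {entry.entry_id}")
    r1, r2 = offset + 1, offset + len(peptide)
    nt1, nt2 = 3 * r1 - 2, 3 * r2
    spans = _edited_spans(sorted(hp.applied_variants, key=lambda a: a.cds_pos))
    ref1 = _edited_to_ref_cds(nt1, spans)
    ref2 = _edited_to_ref_cds(nt2, spans)
    ref1 = max(1, min(ref1, tx.cds_length))
    ref2 = max(ref1, min(ref2, tx.cds_length))
    return cds_interval_to_genomic(tx, ref1, ref2)


def write_bed12(rows: list[tuple[str, list[tuple[int, int]], str, str]],
                path: str) -> None:
    """Write blocked intervals as BED12 (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, intervals, name, strand in rows:
            intervals = sorted(intervals)
            start = intervals[0][0] - 1
            end = intervals[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in intervals)
            starts = ",".join(str(s - 1 - start) for s, e in intervals)
            fh.write("\t".join(map(str, (
                chrom, start, end, name, 0, strand, start, end, "0,0,0",
                len(intervals), sizes, starts))) + "\n")


# ---------------------------------------------------------------------------
# Annotation records
# ---------------------------------------------------------------------------

def build_annotation_records(projections: Iterable[HaplotypeProtein]
                             ) -> pd.DataFrame:
    """One row per haplotype-resolved protein: novelty flag, variant counts
    broken down by SNV/indel and zygosity, variant list, diff string, and
    effect flags."""
    rows = []
    for hp in sorted(projections, key=lambda h: h.entry_id):
        variants = [av.variant for av in hp.applied_variants]
        rows.append({
            "protein_id": hp.entry_id,
            "transcript_id": hp.transcript_id,
            "gene_id": hp.gene_id,
            "haplotype": hp.haplotype_label,
            "is_novel_splice": hp.is_novel_splice,
            "n_het_snv": sum(v.is_het and v.variant_type == "SNV" for v in variants),
            "n_hom_snv": sum((not v.is_het) and v.variant_type == "SNV"
                             for v in variants),
            "n_het_indel": sum(v.is_het and v.variant_type == "indel"
                               for v in variants),
            "n_hom_indel": sum((not v.is_het) and v.variant_type == "indel"
                               for v in variants),
            "variants": ";".join(str(v) for v in variants),
            "diff_string": hp.diff_string,
            "has_indel": hp.flags.has_indel,
            "frameshift": hp.flags.frameshift,
            "resolved_frameshift": hp.flags.resolved_frameshift,
            "changed_stop": hp.flags.changed_stop,
            "changed_start": hp.flags.changed_start,
            "truncated": hp.flags.truncated,
        })
    return pd.DataFrame(rows)
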