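"""Haplotype projection: apply phased variants to transcript CDSs and translate.

For each transcript, both haplotype CDS sequences are built from the phased
variant set, translated with the standard genetic code, and characterized
against the reference protein (indel/frameshift/stop effects, diff string).
Heterozygous products get A/B labels assigned per gene so that haplotypes
carrying the same allele of a shared heterozygous variant keep the same
letter across isoforms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import edlib
from Bio.Data import CodonTable

from .model import (
    Thresholds,
    TranscriptModel,
    Variant,
    genomic_to_cds_coord,
    revcomp,
    spliced_cds_sequence,
    spliced_utr3_sequence,
    variant_overlaps_cds,
)

log = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
_STOP_CODONS = frozenset(_STANDARD.stop_codons)


def translate_cds(nt_seq: str) -> tuple[str, bool, Optional[int]]:
    """Translate with the standard code, stopping at the first terminator.

    Returns ``(aa, stop_observed, stop_codon_index)`` where the index is the
    1-based codon position of the terminator (None when translation runs off
    the end without one). Codons containing N translate to 'X'; a trailing
    incomplete codon is ignored.
    """
    if len(nt_seq) < 3:
        raise ValueError(f"sequence of length {len(nt_seq)} too short to translate")
    aa = []
    for i in range(0, len(nt_seq) - 2, 3):
        codon = nt_seq[i:i + 3]
        if codon in _STOP_CODONS:
            return "".join(aa), True, i // 3 + 1
        aa.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aa), False, None


class TranslationResult(NamedTuple):
    aa: str
    stop_observed: bool
    stop_codon_index: Optional[int]
    n_cds_codons: int  # complete codons available within the (edited) CDS


def _translate_extended(cds_nt: str, utr3_nt: str) -> TranslationResult:
    """Translate the CDS, continuing into downstream exonic sequence if the
    terminator was lost by an edit."""
    aa, stop, idx = translate_cds(cds_nt + utr3_nt if len(cds_nt) >= 3 else cds_nt)
    return TranslationResult(aa, stop, idx, len(cds_nt) // 3)


@dataclass(frozen=True)
class EffectFlags:
    has_indel: bool = False
    frameshift: bool = False
    resolved_frameshift: bool = False
    changed_stop: bool = False
    changed_start: bool = False
    truncated: bool = False


@dataclass
class AppliedVariant:
    """A variant projected into CDS space for one transcript.

    ``cds_pos``/``cds_ref``/``cds_alt`` are in CDS (translation-strand)
    orientation; minus-strand alleles are reverse-complemented. Protein
    coordinates (``protein_start``/``protein_end``, 1-based residues of the
    alt-allele span in the edited protein) are filled per haplotype product.
    """

    variant: Variant
    cds_pos: int
    cds_ref: str
    cds_alt: str
    haplotypes_carrying: frozenset[int]
    protein_start: Optional[int] = None
    protein_end: Optional[int] = None

    @property
    def cds_end(self) -> int:
        return self.cds_pos + len(self.cds_ref) - 1

    @property
    def delta(self) -> int:
        return len(self.cds_alt) - len(self.cds_ref)


@dataclass
class HaplotypeProtein:
    """One translated allele-specific protein product."""

    transcript_id: str
    gene_id: str
    haplotype_label: str  # 'A' | 'B' | 'HOM'
    haplotype_index: Optional[int]  # 1 | 2 | None for HOM
    aa_sequence: str
    applied_variants: list[AppliedVariant] = field(default_factory=list)
    flags: EffectFlags = field(default_factory=EffectFlags)
    diff_string: str = ""
    is_novel_splice: bool = False
    phase_set: Optional[int] = None

    @property
    def entry_id(self) -> str:
        if self.haplotype_label in ("A", "B"):
            return f"{self.transcript_id}.{self.haplotype_label}"
        return self.transcript_id

    @property
    def is_single_haplotype(self) -> bool:
        return self.haplotype_label in ("A", "B")


def map_variant_to_cds(tx: TranscriptModel, v: Variant) -> Optional[AppliedVariant]:
    """Project a variant into CDS coordinates, or None if it cannot be.

    The whole REF span must lie contiguously inside the CDS; edits spanning
    a CDS/intron boundary have no defined projection and are skipped by the
    caller with a warning.
    """
    c_start = genomic_to_cds_coord(tx, v.pos)
    c_end = genomic_to_cds_coord(tx, v.end)
    if c_start is None or c_end is None:
        return None
    lo, hi = min(c_start, c_end), max(c_start, c_end)
    if hi - lo != v.end - v.pos:  # REF span interrupted by an intron
        return None
    if tx.strand == "+":
        cds_ref, cds_alt = v.ref_allele, v.alt_allele
    else:
        cds_ref, cds_alt = revcomp(v.ref_allele), revcomp(v.alt_allele)
    return AppliedVariant(
        variant=v, cds_pos=lo, cds_ref=cds_ref, cds_alt=cds_alt,
        haplotypes_carrying=v.haplotypes_carrying_alt(),
    )


def _check_applied(cds_seq: str, edits: list[AppliedVariant]) -> None:
    prev_end = 0
    for av in sorted(edits, key=lambda a: a.cds_pos):
        if av.cds_pos <= prev_end:
            raise ValueError(f"overlapping edits at CDS position {av.cds_pos}")
        found = cds_seq[av.cds_pos - 1:av.cds_end]
        if found != av.cds_ref:
            raise ValueError(
                f"REF mismatch for {av.variant}: CDS has {found!r}, "
                f"expected {av.cds_ref!r}"
            )
        prev_end = av.cds_end


def apply_variants_to_cds(cds_seq: str, applied: list[AppliedVariant],
                          haplotype: int) -> str:
    """Substitute every edit carried by the chosen haplotype into the CDS.

    Edits are applied in descending CDS position so earlier coordinates
    remain valid as lengths change.
    """
    edits = [a for a in applied if haplotype in a.haplotypes_carrying]
    _check_applied(cds_seq, edits)
    seq = cds_seq
    for av in sorted(edits, key=lambda a: -a.cds_pos):
        seq = seq[:av.cds_pos - 1] + av.cds_alt + seq[av.cds_end:]
    return seq


def _edited_spans(edits: list[AppliedVariant]) -> list[tuple[AppliedVariant, int, int]]:
    """Alt-allele nucleotide spans of each edit in edited-CDS coordinates."""
    out = []
    offset = 0
    for av in sorted(edits, key=lambda a: a.cds_pos):
        start = av.cds_pos + offset
        end = start + len(av.cds_alt) - 1
        out.append((av, start, end))
        offset += av.delta
    return out


def characterize_effects(ref_protein: str, alt_protein: str,
                         applied: list[AppliedVariant],
                         ref_tr: TranslationResult,
                         alt_tr: TranslationResult) -> tuple[EffectFlags, str]:
    """Flag protein-level consequences and build the reference diff string.

    Frameshift status comes from the cumulative length offset of the edits
    scanned left to right: a final offset not divisible by 3 is a
    frameshift; a mid-scan offset that is non-zero mod 3 but ends divisible
    by 3 is a resolved frameshift. The stop is "changed" when the
    terminator is not at the final codon of the edited CDS (premature,
    lost, or pushed into downstream exonic sequence).
    """
    running, cum = [], 0
    for av in sorted(applied, key=lambda a: a.cds_pos):
        cum += av.delta
        running.append(cum)
    frameshift = bool(running) and running[-1] % 3 != 0
    resolved = (not frameshift) and any(r % 3 != 0 for r in running[:-1])
    changed_stop = (not alt_tr.stop_observed) or (
        alt_tr.stop_codon_index != alt_tr.n_cds_codons)
    truncated = (not alt_tr.stop_observed) or (
        alt_tr.stop_codon_index < alt_tr.n_cds_codons)
    flags = EffectFlags(
        has_indel=any(a.variant.variant_type == "indel" for a in applied),
        frameshift=frameshift,
        resolved_frameshift=resolved,
        changed_stop=changed_stop,
        changed_start=bool(alt_protein) and bool(ref_protein)
        and alt_protein[0] != ref_protein[0],
        truncated=truncated,
    )
    return flags, diff_string(ref_protein, alt_protein)


def diff_string(ref: str, alt: str) -> str:
    """Compact residue-level diff between reference and alternate proteins.

    Length-preserving changes are listed as ``<ref><pos><alt>`` (e.g.
    ``K2E``); otherwise a minimal alignment is rendered as substitutions
    plus ``del<pos><residues>`` / ``ins<pos><residues>`` events, with
    positions 1-based on the reference.
    """
    if ref == alt:
        return ""
    if len(ref) == len(alt):
        return ";".join(f"{r}{i}{a}" for i, (r, a)
                        in enumerate(zip(ref, alt), start=1) if r != a)
    cigar = edlib.align(alt, ref, task="path")["cigar"]
    ops: list[str] = []
    ri = ai = 0  # 0-based cursors on ref and alt
    for count, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(count)
        if op == "=":
            ri += n
            ai += n
        elif op == "X":
            for k in range(n):
                ops.append(f"{ref[ri + k]}{ri + k + 1}{alt[ai + k]}")
            ri += n
            ai += n
        elif op == "D":  # present in ref, absent in alt
            ops.append(f"del{ri + 1}{ref[ri:ri + n]}")
            ri += n
        else:  # 'I': present in alt only; anchored at next ref position
            ops.append(f"ins{ri + 1}{alt[ai:ai + n]}")
            ai += n
    return ";".join(ops)


def project_transcript_haplotypes(genome: dict[str, str], tx: TranscriptModel,
                                  variants: list[Variant], th: Thresholds
                                  ) -> list[HaplotypeProtein]:
    """Build the haplotype protein products of one transcript.

    Expects variants that already passed the processing chain (all hets
    overlapping this CDS share one phase set). Silent variants are excluded
    from ``applied_variants``; identical haplotype products collapse into a
    single HOM entry; products shorter than the minimum codon length
    (min_cds_nt / 3) are dropped.
    """
    cds_seq = spliced_cds_sequence(genome, tx)
    utr3 = spliced_utr3_sequence(genome, tx)
    ref_tr = _translate_extended(cds_seq, utr3)

    overlapping = [v for v in variants
                   if v.chrom == tx.chrom and variant_overlaps_cds(tx, v)]
    hets = [v for v in overlapping if v.is_het]
    for v in hets:
        if not v.phased:
            raise ValueError(
                f"unphased heterozygous variant {v} reached projection of "
                f"{tx.transcript_id}; run the variant-processing chain first")
    phase_sets = {v.phase_set for v in hets}
    if len(phase_sets) > 1:
        raise ValueError(
            f"hets of {tx.transcript_id} span phase sets {phase_sets}")
    phase_set = next(iter(phase_sets)) if phase_sets else None

    applied: list[AppliedVariant] = []
    for v in overlapping:
        av = map_variant_to_cds(tx, v)
        if av is None:
            log.warning("variant %s spans a CDS boundary of %s; skipped",
                        v, tx.transcript_id)
            continue
        applied.append(av)
    applied.sort(key=lambda a: a.cds_pos)
    _check_applied(cds_seq, applied)

    # Silent = applied alone, the protein is unchanged. Silent variants are
    # still substituted into the haplotype sequence (a third-base change can
    # matter downstream of a frameshift); they are only excluded from the
    # applied-variant annotation.
    silent_keys = set()
    for av in applied:
        lone = apply_variants_to_cds(cds_seq, [av], min(av.haplotypes_carrying))
        if _translate_extended(lone, utr3).aa == ref_tr.aa:
            silent_keys.add(av.variant.key)

    min_codons = th.min_cds_nt // 3
    products: dict[int, tuple[str, TranslationResult, list[AppliedVariant]]] = {}
    for hap in (1, 2):
        carried = [a for a in applied if hap in a.haplotypes_carrying]
        edited = apply_variants_to_cds(cds_seq, carried, hap)
        tr = _translate_extended(edited, utr3)
        if len(tr.aa) < min_codons:
            log.info("haplotype %d of %s shorter than %d codons; dropped",
                     hap, tx.transcript_id, min_codons)
            continue
        hap_applied = []
        for av, nt_start, nt_end in _edited_spans(carried):
            if av.variant.key in silent_keys:
                continue
            hap_applied.append(replace(
                av,
                protein_start=(nt_start - 1) // 3 + 1,
                protein_end=(nt_end - 1) // 3 + 1,
            ))
        products[hap] = (tr.aa, tr, hap_applied)

    def make(label: str, hap_index: Optional[int], aa: str, tr: TranslationResult,
             hap_applied: list[AppliedVariant]) -> HaplotypeProtein:
        flags, diff = characterize_effects(ref_tr.aa, aa, hap_applied, ref_tr, tr)
        return HaplotypeProtein(
            transcript_id=tx.transcript_id, gene_id=tx.gene_id,
            haplotype_label=label, haplotype_index=hap_index,
            aa_sequence=aa, applied_variants=hap_applied,
            flags=flags, diff_string=diff,
            phase_set=phase_set,
        )

    if not products:
        return []
    if len(products) == 2 and products[1][0] == products[2][0]:
        aa, tr, hap_applied = products[1]
        both = [a for a in hap_applied if a.haplotypes_carrying == frozenset((1, 2))]
        return [make("HOM", None, aa, tr, both)]
    out = []
    for hap, (aa, tr, hap_applied) in sorted(products.items()):
        out.append(make("A" if hap == 1 else "B", hap, aa, tr, hap_applied))
    return out


def assign_haplotype_labels(entries: list[HaplotypeProtein]) -> None:
    """Reconcile A/B labels per gene across isoforms sharing het variants.

    Transcripts are visited in lexicographic order within each gene; the
    first keeps haplotype 1 = A. Each later transcript is oriented so that,
    at the leftmost heterozygous variant shared with an already-labeled
    isoform, the alt allele stays on the same letter. Entries are relabeled
    in place; HOM entries are untouched. The result is independent of the
    input list order.
    """
    by_gene: dict[str, dict[str, list[HaplotypeProtein]]] = {}
    for e in entries:
        if e.is_single_haplotype:
            by_gene.setdefault(e.gene_id, {}).setdefault(e.transcript_id, []).append(e)
    for gene in sorted(by_gene):
        alt_letter: dict[tuple, str] = {}  # variant key -> letter carrying alt
        for tid in sorted(by_gene[gene]):
            pair = sorted(by_gene[gene][tid], key=lambda e: e.haplotype_index)
            hets = sorted(
                {a.variant.key: a.variant for e in pair
                 for a in e.applied_variants if a.variant.is_het}.values(),
                key=lambda v: (v.chrom, v.pos))
            flip = False
            for v in hets:
                if v.key in alt_letter:
                    hap_alt = min(v.haplotypes_carrying_alt())
                    default_letter = "A" if hap_alt == 1 else "B"
                    flip = default_letter != alt_letter[v.key]
                    break
            for e in pair:
                letter = "A" if e.haplotype_index == 1 else "B"
                if flip:
                    letter = "B" if letter == "A" else "A"
                e.haplotype_label = letter
            for v in hets:
                if v.key not in alt_letter:
                    hap_alt = min(v.haplotypes_carrying_alt())
                    letter = "A" if hap_alt == 1 else "B"
                    if flip:
                        letter = "B" if letter == "A" else "A"
                    alt_letter[v.key] = letter
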