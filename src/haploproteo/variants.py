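"""Post-call variant filtering and CDS phase-block post-processing.

The chain (quality/biallelic filter -> CDS phase-completeness enforcement ->
singleton phase-block assignment) guarantees that, afterwards, every CDS
contains heterozygous variants from at most one phase block — the property
that makes per-transcript haplotype projection well defined.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

from .model import PhaseBlock, Thresholds, TranscriptModel, Variant, variant_overlaps_cds

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Audit counts for one pass of the variant-processing chain."""

    n_input: int = 0
    n_removed_gq: int = 0
    n_removed_multiallelic: int = 0
    n_removed_phase_incomplete: int = 0
    n_singleton_assigned: int = 0
    n_output: int = 0

    def to_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Chain two reports: input of the first, output of the last."""
        return FilterReport(
            n_input=self.n_input,
            n_removed_gq=self.n_removed_gq + other.n_removed_gq,
            n_removed_multiallelic=self.n_removed_multiallelic + other.n_removed_multiallelic,
            n_removed_phase_incomplete=(
                self.n_removed_phase_incomplete + other.n_removed_phase_incomplete),
            n_singleton_assigned=self.n_singleton_assigned + other.n_singleton_assigned,
            n_output=other.n_output,
        )


def filter_variants(variants: list[Variant], th: Thresholds
                    ) -> tuple[list[Variant], FilterReport]:
    """Keep biallelic variants with genotype quality >= the minimum.

    Multi-allelic records (flagged by the reader) are removed first; the
    GQ threshold applies to the rest. Order is preserved.
    """
    rep = FilterReport(n_input=len(variants))
    out = []
    for v in variants:
        if v.multiallelic:
            rep.n_removed_multiallelic += 1
        elif v.genotype_quality < th.min_gq:
            rep.n_removed_gq += 1
        else:
            out.append(v)
    rep.n_output = len(out)
    return out, rep


def _cds_het_index(variants: list[Variant], txs: list[TranscriptModel]
                   ) -> dict[str, list[int]]:
    """Map transcript_id -> indices (into variants) of overlapping het variants."""
    by_chrom: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        if v.is_het:
            by_chrom.setdefault(v.chrom, []).append(i)
    idx: dict[str, list[int]] = {}
    for tx in txs:
        hits = [i for i in by_chrom.get(tx.chrom, [])
                if variant_overlaps_cds(tx, variants[i])]
        if hits:
            idx[tx.transcript_id] = hits
    return idx


def enforce_cds_phase_completeness(variants: list[Variant], txs: list[TranscriptModel]
                                   ) -> tuple[list[Variant], FilterReport]:
    """Remove het variants from CDSs whose hets span more than one phase block.

    For each transcript CDS: if >= 2 heterozygous variants overlap it and
    they are not all phased into one shared phase set, every het in that
    CDS is removed. A het failing in any overlapping CDS is removed
    globally (conservative). Homozygous variants are untouched.
    """
    rep = FilterReport(n_input=len(variants))
    idx = _cds_het_index(variants, txs)
    doomed: set[int] = set()
    for tid, hits in idx.items():
        if len(hits) < 2:
            continue
        ps = {variants[i].phase_set if variants[i].phased else None for i in hits}
        if len(ps) > 1 or None in ps:
            log.debug("CDS of %s spans phase sets %s; removing %d hets", tid, ps, len(hits))
            doomed.update(hits)
    out = [v for i, v in enumerate(variants) if i not in doomed]
    rep.n_removed_phase_incomplete = len(doomed)
    rep.n_output = len(out)
    return out, rep


def assign_singleton_phase_blocks(variants: list[Variant], txs: list[TranscriptModel]
                                  ) -> tuple[list[Variant], FilterReport]:
    """Arbitrarily phase hets that are the sole het of every CDS they touch.

    Phasing is arbitrary for a lone het, so it gets haplotype 1 = alt and a
    fresh phase set equal to its genomic position (collision-free since no
    other het shares its CDS).
    """
    rep = FilterReport(n_input=len(variants), n_output=len(variants))
    idx = _cds_het_index(variants, txs)
    lone: dict[int, bool] = {}
    for hits in idx.values():
        sole = len(hits) == 1
        for i in hits:
            lone[i] = lone.get(i, True) and sole
    out = list(variants)
    for i, is_lone in lone.items():
        v = variants[i]
        if is_lone and not v.phased:
            out[i] = dataclasses.replace(
                v, phased=True, genotype=(1, 0), phase_set=v.pos)
            rep.n_singleton_assigned += 1
    return out, rep


def process_variants(variants: list[Variant], txs: list[TranscriptModel],
                     th: Thresholds) -> tuple[list[Variant], FilterReport]:
    """Run the full post-call chain: filter -> enforce -> assign singletons."""
    v1, r1 = filter_variants(variants, th)
    v2, r2 = enforce_cds_phase_completeness(v1, txs)
    v3, r3 = assign_singleton_phase_blocks(v2, txs)
    return v3, r1.merge(r2).merge(r3)


def build_phase_blocks(variants: list[Variant]) -> list[PhaseBlock]:
    """Group phased heterozygous variants into (chrom, phase set) blocks."""
    members: dict[tuple[str, int], list[int]] = {}
    for v in variants:
        if v.is_het and v.phased and v.phase_set is not None:
            members.setdefault((v.chrom, v.phase_set), []).append(v.pos)
    return [PhaseBlock(phase_set=ps, chrom=chrom, member_positions=pos)
            for (chrom, ps), pos in sorted(members.items())]
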