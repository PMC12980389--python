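"""Phasing accuracy and completeness metrics.

Switch error rate over consecutive heterozygous pairs, phased-variant
counts, and fully-phased region fractions at CDS, transcript, and gene
resolution — the benchmark layer for comparing read-based phasers on
transcript data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import TranscriptModel, Variant

log = logging.getLogger(__name__)


@dataclass
class PhasingMetrics:
    n_switches: int = 0
    n_assessed_pairs: int = 0
    switch_error_rate: float = 0.0
    n_phased_het: int = 0
    n_het_total: int = 0
    fully_phased_fraction: dict[str, float] = field(default_factory=dict)


def switch_error_rate(truth: list[Variant], test: list[Variant]
                      ) -> tuple[int, int, float]:
    """Switch errors over consecutive shared het pairs, pooled over blocks.

    Comparison is restricted to sites heterozygous and phased in both call
    sets; sites with discordant zygosity are excluded and logged. A pair is
    assessed only when both sites share a phase set in the test AND in the
    truth (relative orientation is undefined across blocks); a switch is a
    change of relative haplotype orientation between the pair's two sites.
    The rate is invariant under a global haplotype flip.
    """
    truth_idx = {v.key: v for v in truth if v.phased}
    n_switches = n_pairs = 0
    blocks: dict[tuple[str, int], list[tuple[int, bool, int]]] = {}
    for v in test:
        if not (v.is_het and v.phased and v.phase_set is not None):
            continue
        t = truth_idx.get(v.key)
        if t is None:
            continue
        if not t.is_het:
            log.warning("site %s het in test but hom in truth; excluded", v)
            continue
        orientation = v.genotype == t.genotype
        blocks.setdefault((v.chrom, v.phase_set), []).append(
            (v.pos, orientation, t.phase_set))
    for sites in blocks.values():
        sites.sort()
        for (p1, o1, ps1), (p2, o2, ps2) in zip(sites, sites[1:]):
            if ps1 != ps2:
                continue
            n_pairs += 1
            if o1 != o2:
                n_switches += 1
    rate = n_switches / n_pairs if n_pairs else 0.0
    return n_switches, n_pairs, rate


def completeness_counts(test: list[Variant]) -> tuple[int, int]:
    """(phased hets, total hets)."""
    hets = [v for v in test if v.is_het]
    return sum(v.phased for v in hets), len(hets)


def _regions(txs: list[TranscriptModel], level: str
             ) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """region id -> (chrom, intervals). CDS/transcript are per isoform
    (CDS union / exon union); gene aggregates the CDS bases of all its
    isoforms."""
    if level == "CDS":
        return {tx.transcript_id: (tx.chrom, tx.cds) for tx in txs if tx.cds}
    if level == "transcript":
        return {tx.transcript_id: (tx.chrom, tx.exons) for tx in txs if tx.exons}
    if level == "gene":
        out: dict[str, tuple[str, list[tuple[int, int]]]] = {}
        for tx in txs:
            chrom, ivs = out.get(tx.gene_id, (tx.chrom, []))
            out[tx.gene_id] = (chrom, ivs + list(tx.cds))
        return out
    raise ValueError(f"unknown region level {level!r}")


def fully_phased_fraction(test: list[Variant], txs: list[TranscriptModel],
                          level: str = "CDS"
                          ) -> tuple[float, float, pd.DataFrame]:
    """Fraction of regions whose het variants form one contiguous phase block.

    A region is fully phased when all overlapping hets are phased into a
    single phase set; regions with 0 or 1 het count as fully phased.
    Returns (fraction over all regions, fraction over regions with >= 1
    het, per-region table).
    """
    hets = [v for v in test if v.is_het]
    rows = []
    for rid, (chrom, intervals) in sorted(_regions(txs, level).items()):
        overlapping = [v for v in hets if v.chrom == chrom
                       and any(v.pos <= e and v.end >= s for s, e in intervals)]
        if len(overlapping) <= 1:
            full = True
        else:
            ps = {v.phase_set if v.phased else None for v in overlapping}
            full = len(ps) == 1 and None not in ps
        rows.append({"region": rid, "level": level,
                     "n_het": len(overlapping), "fully_phased": full})
    table = pd.DataFrame(rows)
    if table.empty:
        return 1.0, 1.0, table
    frac_all = float(table.fully_phased.mean())
    with_hets = table[table.n_het > 0]
    frac_hets = float(with_hets.fully_phased.mean()) if len(with_hets) else 1.0
    return frac_all, frac_hets, table


def compute_metrics(test: list[Variant], txs: list[TranscriptModel],
                    truth: list[Variant] | None = None) -> PhasingMetrics:
    m = PhasingMetrics()
    if truth is not None:
        m.n_switches, m.n_assessed_pairs, m.switch_error_rate = \
            switch_error_rate(truth, test)
    m.n_phased_het, m.n_het_total = completeness_counts(test)
    for level in ("CDS", "transcript", "gene"):
        frac_all, frac_hets, _ = fully_phased_fraction(test, txs, level)
        m.fully_phased_fraction[level] = frac_all
        m.fully_phased_fraction[level + "_with_het"] = frac_hets
    return m


def stratify_by_coverage(variants: list[Variant],
                         coverage: dict[tuple[str, int], int],
                         cutoffs: list[int],
                         txs: list[TranscriptModel],
                         truth: list[Variant] | None = None) -> pd.DataFrame:
    """Recompute all metrics per minimum-coverage cutoff and variant stratum.

    Sites absent from the coverage map count as depth 0. Strata are
    SNV-only and SNV+indel, matching the benchmark's stratification.
    """
    rows = []
    for cutoff in cutoffs:
        passing = [v for v in variants
                   if coverage.get((v.chrom, v.pos), 0) >= cutoff]
        for stratum, subset in (
                ("SNV", [v for v in passing if v.variant_type == "SNV"]),
                ("SNV+indel", passing)):
            m = compute_metrics(subset, txs, truth)
            row = {"min_coverage": cutoff, "stratum": stratum,
                   "n_switches": m.n_switches,
                   "n_assessed_pairs": m.n_assessed_pairs,
                   "switch_error_rate": m.switch_error_rate,
                   "n_phased_het": m.n_phased_het,
                   "n_het_total": m.n_het_total}
            row.update({f"fully_phased_{k}": v
                        for k, v in m.fully_phased_fraction.items()})
            rows.append(row)
    return pd.DataFrame(rows)
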