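"""Seeded synthetic fixtures: genome, annotation, phased variants, PSMs.

Every generator is byte-deterministic given its seed and carries its ground
truth along. Haplotype truth sequences are built by editing the genome
directly in genome space and re-extracting the spliced CDS — a path
independent of the CDS-space projection engine, which is exactly what makes
them usable as an oracle for it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from Bio.Seq import Seq

from .database import ProteinDatabaseEntry, tryptic_digest
from .model import (
    Thresholds,
    TranscriptModel,
    Variant,
    genomic_to_cds_coord,
    revcomp,
)

_NT = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationTruth:
    """Ground truth carried alongside a simulated variant set."""

    planted_variants: list[Variant] = field(default_factory=list)
    haplotype_sequences: dict[str, tuple[str, str]] = field(default_factory=dict)
    expected_proteins: dict[str, tuple[str, str]] = field(default_factory=dict)
    planted_switches: list[tuple[tuple[str, int], int]] = field(default_factory=list)


def _random_codon(rng: random.Random) -> str:
    while True:
        codon = "".join(rng.choice(_NT) for _ in range(3))
        if codon not in _STOPS and codon != "ATG":
            return codon


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_NT) for _ in range(n))


def simulate_reference(seed: int, n_genes: int = 10, exons_per_tx: int = 3,
                       cds_len_range: tuple[int, int] = (150, 300),
                       utr_len: int = 40, intron_len: int = 50,
                       gap: int = 60, genes_per_chrom: int = 5,
                       ) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Simulate a genome and one coding transcript per gene.

    Transcripts alternate strand, are multi-exon, begin with ATG and end
    with a terminator codon; CDS lengths are multiples of 3 within the
    requested range.
    """
    lo, hi = cds_len_range
    if lo < 9 or hi < lo:
        raise ValueError(f"infeasible cds_len_range {cds_len_range}")
    if exons_per_tx < 1 or n_genes < 1:
        raise ValueError("need >= 1 gene and >= 1 exon per transcript")
    rng = random.Random(seed)
    chroms: dict[str, str] = {}
    txs: list[TranscriptModel] = []
    for i in range(n_genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        strand = "+" if i % 2 == 0 else "-"
        n_codons = rng.randrange(lo // 3, hi // 3 + 1)
        cds = "ATG" + "".join(_random_codon(rng) for _ in range(n_codons - 2)) \
            + rng.choice(_STOPS)
        tx_seq = _random_seq(rng, utr_len) + cds + _random_seq(rng, utr_len)
        # split the mature transcript into exons at random internal cuts
        n_cuts = exons_per_tx - 1
        cuts = sorted(rng.sample(range(10, len(tx_seq) - 10), n_cuts)) if n_cuts else []
        bounds = [0] + cuts + [len(tx_seq)]
        exon_seqs = [tx_seq[a:b] for a, b in zip(bounds, bounds[1:])]
        locus = ""
        exon_spans_locus = []  # 1-based within locus, transcript orientation
        for j, es in enumerate(exon_seqs):
            if j:
                locus += _random_seq(rng, intron_len)
            exon_spans_locus.append((len(locus) + 1, len(locus) + len(es)))
            locus += es
        cds_tx_span = (utr_len + 1, utr_len + len(cds))  # transcript coords

        # transcript-coordinate -> locus-coordinate pieces of the CDS
        cds_spans_locus = []
        tx_pos = 0
        for (ls, le), es in zip(exon_spans_locus, exon_seqs):
            ex_tx = (tx_pos + 1, tx_pos + len(es))
            ov_s = max(ex_tx[0], cds_tx_span[0])
            ov_e = min(ex_tx[1], cds_tx_span[1])
            if ov_s <= ov_e:
                cds_spans_locus.append((ls + ov_s - ex_tx[0], ls + ov_e - ex_tx[0]))
            tx_pos += len(es)

        prev = chroms.get(chrom, _random_seq(rng, gap))
        offset = len(prev)
        L = len(locus)
        if strand == "+":
            genomic = locus
            to_genomic = lambda s, e: (offset + s, offset + e)
        else:
            genomic = revcomp(locus)
            to_genomic = lambda s, e: (offset + L - e + 1, offset + L - s + 1)
        chroms[chrom] = prev + genomic + _random_seq(rng, gap)
        gid = f"G{i + 1:03d}"
        txs.append(TranscriptModel(
            transcript_id=f"T{i + 1:03d}", gene_id=gid, chrom=chrom,
            strand=strand,
            exons=sorted(to_genomic(s, e) for s, e in exon_spans_locus),
            cds=sorted(to_genomic(s, e) for s, e in cds_spans_locus),
        ))
    return chroms, txs


def _candidate_positions(tx: TranscriptModel, span_needed: int) -> list[int]:
    """Genomic starts where a REF span fits inside one CDS interval, away
    from the start/stop codons."""
    total = tx.cds_length
    out = []
    for s, e in tx.cds:
        for p in range(s, e - span_needed + 2):
            c1 = genomic_to_cds_coord(tx, p)
            c2 = genomic_to_cds_coord(tx, p + span_needed - 1)
            lo, hi = min(c1, c2), max(c1, c2)
            if lo > 4 and hi < total - 3:
                out.append(p)
    return out


def simulate_phased_variants(seed: int, genome: dict[str, str],
                             txs: list[TranscriptModel],
                             n_het_snv: int = 2, n_hom_snv: int = 1,
                             n_het_indel: int = 0, n_hom_indel: int = 0,
                             indel_len_range: tuple[int, int] = (1, 6),
                             phase_structure: str = "single",
                             gq: float = 60.0,
                             ) -> tuple[list[Variant], SimulationTruth]:
    """Plant CDS variants per transcript and build genome-edited truth.

    Counts are per transcript; indel lengths (inserted or deleted
    nucleotides beyond the anchor base) are drawn uniformly from
    ``indel_len_range``, producing both in-frame and frameshifting edits.
    ``phase_structure`` is ``single`` (one phase block per transcript) or
    ``fragmented`` (hets split across two blocks, for testing the
    completeness filter).
    """
    rng = random.Random(seed)
    truth = SimulationTruth()
    max_indel = indel_len_range[1]
    spacing = 2 * max_indel + 4
    for tx in txs:
        chrom_seq = genome[tx.chrom]
        taken: list[tuple[int, int]] = []

        def place(span: int) -> Optional[int]:
            cands = [p for p in _candidate_positions(tx, span)
                     if all(p + span - 1 < s - spacing or p > e + spacing
                            for s, e in taken)]
            if not cands:
                return None
            p = rng.choice(cands)
            taken.append((p, p + span - 1))
            return p

        planted: list[Variant] = []
        specs = ([("SNV", True)] * n_het_snv + [("SNV", False)] * n_hom_snv
                 + [("indel", True)] * n_het_indel + [("indel", False)] * n_hom_indel)
        for vtype, het in specs:
            if vtype == "SNV":
                p = place(1)
                if p is None:
                    continue
                ref = chrom_seq[p - 1]
                alt = rng.choice([b for b in _NT if b != ref])
            else:
                d = rng.randrange(indel_len_range[0], indel_len_range[1] + 1)
                if rng.random() < 0.5:  # insertion
                    p = place(1)
                    if p is None:
                        continue
                    ref = chrom_seq[p - 1]
                    alt = ref + _random_seq(rng, d)
                else:  # deletion
                    p = place(d + 1)
                    if p is None:
                        continue
                    ref = chrom_seq[p - 1:p + d]
                    alt = ref[0]
            genotype = rng.choice([(0, 1), (1, 0)]) if het else (1, 1)
            planted.append(Variant(
                chrom=tx.chrom, pos=p, ref_allele=ref, alt_allele=alt,
                genotype=genotype, phased=het, phase_set=None,
                genotype_quality=gq))
        planted.sort(key=lambda v: v.pos)
        hets = [v for v in planted if v.is_het]
        if hets:
            if phase_structure == "fragmented" and len(hets) >= 2:
                cut = len(hets) // 2
                for v in hets[:cut]:
                    v.phase_set = hets[0].pos
                for v in hets[cut:]:
                    v.phase_set = hets[cut].pos
            else:
                for v in hets:
                    v.phase_set = hets[0].pos
        truth.planted_variants.extend(planted)
        nt1, aa1 = _truth_haplotype(genome, tx, planted, 1)
        nt2, aa2 = _truth_haplotype(genome, tx, planted, 2)
        truth.haplotype_sequences[tx.transcript_id] = (nt1, nt2)
        truth.expected_proteins[tx.transcript_id] = (aa1, aa2)
    return list(truth.planted_variants), truth


def _shift_intervals(intervals: list[tuple[int, int]], pos: int, end: int,
                     delta: int) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        if s > end:
            out.append((s + delta, e + delta))
        elif s <= pos and end <= e:
            out.append((s, e + delta))
        else:
            out.append((s, e))
    return out


def _truth_haplotype(genome: dict[str, str], tx: TranscriptModel,
                     variants: list[Variant], hap: int) -> tuple[str, str]:
    """Haplotype CDS and protein by direct genome editing (oracle path).

    Applies the haplotype's genomic edits to the chromosome, shifts the
    exon/CDS intervals accordingly, re-extracts the spliced CDS, and
    translates with Biopython, continuing into the 3' exonic sequence when
    an edit removed the terminator.
    """
    chrom_seq = genome[tx.chrom]
    cds = list(tx.cds)
    exons = list(tx.exons)
    edits = [v for v in variants if hap in v.haplotypes_carrying_alt()]
    for v in sorted(edits, key=lambda v: -v.pos):
        delta = len(v.alt_allele) - len(v.ref_allele)
        assert chrom_seq[v.pos - 1:v.end] == v.ref_allele
        chrom_seq = chrom_seq[:v.pos - 1] + v.alt_allele + chrom_seq[v.end:]
        cds = _shift_intervals(cds, v.pos, v.end, delta)
        exons = _shift_intervals(exons, v.pos, v.end, delta)

    order = cds if tx.strand == "+" else list(reversed(cds))
    pieces = [chrom_seq[s - 1:e] for s, e in order]
    if tx.strand == "-":
        pieces = [revcomp(p) for p in pieces]
    cds_nt = "".join(pieces)

    if tx.strand == "+":
        cds_end = max(e for _, e in cds)
        utr_ivs = [(max(s, cds_end + 1), e) for s, e in exons if e > cds_end]
        utr3 = "".join(chrom_seq[s - 1:e] for s, e in utr_ivs if s <= e)
    else:
        cds_start = min(s for s, _ in cds)
        utr_ivs = [(s, min(e, cds_start - 1)) for s, e in reversed(exons)
                   if s < cds_start]
        utr3 = "".join(revcomp(chrom_seq[s - 1:e]) for s, e in utr_ivs if s <= e)

    full = cds_nt + utr3
    full = full[:len(full) // 3 * 3]
    aa = str(Seq(full).translate(to_stop=True))
    return cds_nt, aa


def plant_switch_errors(variants: list[Variant], seed: int, n_switches: int
                        ) -> tuple[list[Variant], list[tuple[tuple[str, int], int]]]:
    """Flip haplotype orientation at random block-internal boundaries.

    Each planted switch flips the genotypes of all block members from a
    chosen pair boundary onward, producing exactly one orientation change
    there. Returns the perturbed copy and the (block, boundary index) list.
    """
    rng = random.Random(seed)
    import dataclasses
    out = [dataclasses.replace(v) for v in variants]
    blocks: dict[tuple[str, int], list[int]] = {}
    for i, v in enumerate(out):
        if v.is_het and v.phased and v.phase_set is not None:
            blocks.setdefault((v.chrom, v.phase_set), []).append(i)
    candidates = []
    for key, idxs in sorted(blocks.items()):
        idxs.sort(key=lambda i: out[i].pos)
        candidates.extend((key, b) for b in range(1, len(idxs)))
    if n_switches > len(candidates):
        raise ValueError(
            f"cannot plant {n_switches} switches; only {len(candidates)} "
            "pair boundaries available")
    planted = sorted(rng.sample(candidates, n_switches))
    for key, boundary in planted:
        idxs = sorted(blocks[key], key=lambda i: out[i].pos)
        for i in idxs[boundary:]:
            g = out[i].genotype
            out[i].genotype = (g[1], g[0])
    return out, planted


def simulate_search_results(seed: int, entries: list[ProteinDatabaseEntry],
                            coverage_fraction: float = 1.0,
                            n_noise_decoy: int = 0, n_noise_highq: int = 0,
                            th: Thresholds = Thresholds()) -> pd.DataFrame:
    """Simulate an FDR-annotated PSM table from the search database.

    Samples the requested fraction of the target tryptic peptide universe
    with q-values drawn uniformly below 0.005 (clearly accepted), plus
    optional noise: decoy-only peptides at low q and target peptides just
    above the 0.01 cutoff — both of which downstream filtering must drop.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in [0,1]")
    rng = random.Random(seed)
    digest = lambda s: tryptic_digest(
        s, th.max_missed_cleavages, th.min_peptide_len, th.max_peptide_len)
    target_peps: set[str] = set()
    decoy_peps: set[str] = set()
    for e in entries:
        (decoy_peps if e.is_decoy else target_peps).update(digest(e.aa_sequence))
    decoy_only = sorted(decoy_peps - target_peps)

    def matches(pep: str) -> str:
        return ";".join(sorted(e.entry_id for e in entries
                               if pep in e.aa_sequence))

    universe = sorted(target_peps)
    n_take = round(coverage_fraction * len(universe))
    chosen = sorted(rng.sample(universe, n_take))
    rows = [{"peptide": p, "q_value": round(rng.uniform(0.0, 0.005), 6),
             "proteins": matches(p)} for p in chosen]
    for p in rng.sample(decoy_only, min(n_noise_decoy, len(decoy_only))):
        rows.append({"peptide": p, "q_value": round(rng.uniform(0.0, 0.005), 6),
                     "proteins": matches(p)})
    leftover = sorted(set(universe) - set(chosen)) or universe
    for _ in range(n_noise_highq):
        pep = rng.choice(leftover)
        rows.append({"peptide": pep,
                     "q_value": round(rng.uniform(0.011, 0.1), 6),
                     "proteins": matches(pep)})
    return pd.DataFrame(rows, columns=["peptide", "q_value", "proteins"])
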