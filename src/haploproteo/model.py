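"""Coordinate-aware genomic data model.

Transcript models, phased variants, and the transcript<->genome coordinate
algebra that haplotype projection is built on. All genomic coordinates are
1-based inclusive (GTF/VCF convention); BED exports are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_NT = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Thresholds:
    """Pipeline-wide filtering and digestion parameters.

    Defaults are the workflow's operating point: genotype quality >= 5,
    CDS length >= 100 nt, PSM q-value < 0.01, tryptic digestion with at
    most two missed cleavages and peptide lengths 5-100, and up to 100
    decoy shuffling iterations. The ``caller_*`` values document the
    upstream variant-caller settings (Clair3-RNA-style) for provenance;
    they act inside the caller and are not re-applied here.
    """

    min_gq: float = 5.0
    min_cds_nt: int = 100
    psm_q_max: float = 0.01
    max_missed_cleavages: int = 2
    min_peptide_len: int = 5
    max_peptide_len: int = 100
    max_decoy_iterations: int = 100
    caller_min_af_snv: float = 0.08
    caller_min_af_indel: float = 0.15
    caller_min_coverage: int = 3
    caller_min_mapq: int = 5

    def __post_init__(self) -> None:
        if self.min_peptide_len > self.max_peptide_len:
            raise ValueError("min_peptide_len must be <= max_peptide_len")


@dataclass
class TranscriptModel:
    """One isoform: exon and CDS intervals on a chromosome strand.

    Intervals are 1-based inclusive ``(start, end)`` tuples, stored sorted
    by genomic start and pairwise non-overlapping regardless of strand.
    The CDS includes the stop codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for ivs in (self.exons, self.cds):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping intervals in {self.transcript_id}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_contains(self, gpos: int) -> bool:
        return any(s <= gpos <= e for s, e in self.cds)


@dataclass
class Variant:
    """One biallelic site from a single-sample phased VCF.

    ``genotype`` is the ordered pair of allele indices (0=ref, 1=alt);
    when ``phased`` the order is the haplotype assignment (haplotype 1,
    haplotype 2). Multi-allelic records are retained by the reader with
    ``multiallelic=True`` for downstream removal; only the first ALT is
    kept in that case.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: tuple[int, int]
    phased: bool = False
    phase_set: Optional[int] = None
    genotype_quality: float = 0.0
    multiallelic: bool = False

    @property
    def variant_type(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        return "indel"

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def is_hom_alt(self) -> bool:
        return self.genotype == (1, 1)

    @property
    def zygosity(self) -> str:
        return "heterozygous" if self.is_het else "homozygous"

    @property
    def end(self) -> int:
        """Last genomic position covered by the REF allele."""
        return self.pos + len(self.ref_allele) - 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def haplotypes_carrying_alt(self) -> frozenset[int]:
        return frozenset(h for h, a in zip((1, 2), self.genotype) if a == 1)

    def __str__(self) -> str:  # used in annotation records
        return f"{self.chrom}:{self.pos}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class PhaseBlock:
    """A set of co-phased heterozygous variants sharing one PS tag."""

    phase_set: int
    chrom: str
    member_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.member_positions = sorted(self.member_positions)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genome(path: str) -> dict[str, str]:
    """Read a genome FASTA into a chrom -> upper-case sequence map."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id} in {path}")
        bad = set(seq) - VALID_NT
        if bad:
            raise ValueError(f"invalid nucleotides {sorted(bad)} in record {rec.id}")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def _merge_adjacent(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or directly abutting 1-based inclusive intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_transcripts(path: str) -> list[TranscriptModel]:
    """Read transcript models from a GTF.

    One model per transcript carrying at least one CDS feature; transcripts
    without CDS are skipped. ``stop_codon`` features are merged into the CDS
    so the terminator is part of the coding model.
    """
    db = gffutils.create_db(
        path, ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError:
            raise ValueError(
                f"{feat.featuretype} feature at {feat.seqid}:{feat.start} "
                "lacks transcript_id"
            ) from None
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start, feat.end))
        else:
            cds.setdefault(tid, []).append((feat.start, feat.end))
    out = []
    for tid in sorted(cds):
        gid, chrom, strand = meta[tid]
        out.append(TranscriptModel(
            transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
            exons=_merge_adjacent(exons.get(tid, [])),
            cds=_merge_adjacent(cds[tid]),
        ))
    return out


def read_phased_variants(path: str) -> list[Variant]:
    """Read a single-sample VCF with GT/GQ (and PS on phased records).

    Multi-allelic records are kept with the flag set so the downstream
    filter can count their removal; multi-sample files are rejected
    because the workflow is sample-specific.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if len(samples) != 1:
        raise ValueError(f"expected a single-sample VCF, found {len(samples)} samples")
    out: list[Variant] = []
    for rec in vf:
        call = rec.samples[0]
        gt = call.get("GT")
        if gt is None or any(a is None for a in gt):
            raise ValueError(f"missing GT at {rec.chrom}:{rec.pos}")
        if len(gt) != 2:
            raise ValueError(f"non-diploid GT at {rec.chrom}:{rec.pos}")
        alts = rec.alts or ()
        if not alts:
            continue
        gq = call.get("GQ")
        ps = call.get("PS")
        phased = bool(call.phased)
        out.append(Variant(
            chrom=rec.chrom, pos=rec.pos,
            ref_allele=rec.ref.upper(), alt_allele=alts[0].upper(),
            genotype=(gt[0], gt[1]),
            phased=phased,
            phase_set=int(ps) if (phased and ps is not None) else None,
            genotype_quality=float(gq) if gq is not None else 0.0,
            multiallelic=len(alts) > 1,
        ))
    return out


# ---------------------------------------------------------------------------
# Writers (plain-text standard formats; consumed back by the readers above)
# ---------------------------------------------------------------------------

def write_genome_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(txs: Iterable[TranscriptModel], path: str, source: str = "haploproteo") -> None:
    with open(path, "w") as fh:
        for tx in txs:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            span = (min(s for s, _ in tx.exons), max(e for _, e in tx.exons))
            fh.write("\t".join(map(str, (
                tx.chrom, source, "transcript", span[0], span[1],
                ".", tx.strand, ".", attrs))) + "\n")
            for s, e in tx.exons:
                fh.write("\t".join(map(str, (
                    tx.chrom, source, "exon", s, e, ".", tx.strand, ".", attrs))) + "\n")
            for s, e in tx.cds:
                fh.write("\t".join(map(str, (
                    tx.chrom, source, "CDS", s, e, ".", tx.strand, ".", attrs))) + "\n")


def write_vcf(variants: Iterable[Variant], path: str,
              contigs: Optional[dict[str, int]] = None,
              sample: str = "SAMPLE") -> None:
    """Write variants as a minimal single-sample VCF (GT:GQ[:PS])."""
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        sep = "|" if v.phased else "/"
        gt = f"{v.genotype[0]}{sep}{v.genotype[1]}"
        gq = int(round(v.genotype_quality))
        if v.phased and v.phase_set is not None:
            fmt, val = "GT:GQ:PS", f"{gt}:{gq}:{v.phase_set}"
        else:
            fmt, val = "GT:GQ", f"{gt}:{gq}"
        lines.append("\t".join(map(str, (
            v.chrom, v.pos, ".", v.ref_allele, v.alt_allele, ".", ".", ".",
            fmt, val))))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_protein_fasta(entries: Iterable[tuple[str, str]], path: str, width: int = 60) -> None:
    """Write (identifier, amino-acid sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for ident, seq in entries:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Coordinate algebra
# ---------------------------------------------------------------------------

def _cds_in_translation_order(tx: TranscriptModel) -> list[tuple[int, int]]:
    return tx.cds if tx.strand == "+" else list(reversed(tx.cds))


def spliced_cds_sequence(genome: dict[str, str], tx: TranscriptModel) -> str:
    """Spliced CDS nucleotide sequence in translation (5'->3' mRNA) order."""
    chrom = genome[tx.chrom]
    pieces = []
    for s, e in _cds_in_translation_order(tx):
        if s < 1 or e > len(chrom):
            raise ValueError(
                f"CDS interval ({s},{e}) of {tx.transcript_id} outside {tx.chrom}"
            )
        piece = chrom[s - 1:e]
        pieces.append(piece if tx.strand == "+" else revcomp(piece))
    return "".join(pieces)


def spliced_utr3_sequence(genome: dict[str, str], tx: TranscriptModel) -> str:
    """Exonic sequence downstream of the CDS in translation order (3' UTR).

    Used to extend translation when an edit removes the stop codon.
    """
    if not tx.cds:
        return ""
    chrom = genome[tx.chrom]
    if tx.strand == "+":
        cds_end = max(e for _, e in tx.cds)
        ivs = [(max(s, cds_end + 1), e) for s, e in tx.exons if e > cds_end]
        return "".join(chrom[s - 1:e] for s, e in ivs if s <= e)
    cds_start = min(s for s, _ in tx.cds)
    ivs = [(s, min(e, cds_start - 1)) for s, e in reversed(tx.exons) if s < cds_start]
    return "".join(revcomp(chrom[s - 1:e]) for s, e in ivs if s <= e)


def genomic_to_cds_coord(tx: TranscriptModel, gpos: int) -> Optional[int]:
    """Map a genomic position to its 1-based CDS coordinate, or None."""
    offset = 0
    for s, e in _cds_in_translation_order(tx):
        if s <= gpos <= e:
            return offset + (gpos - s + 1 if tx.strand == "+" else e - gpos + 1)
        offset += e - s + 1
    return None


def cds_coord_to_genomic(tx: TranscriptModel, cpos: int) -> int:
    """Map a 1-based CDS coordinate to its genomic position."""
    if cpos < 1 or cpos > tx.cds_length:
        raise ValueError(f"CDS position {cpos} out of range for {tx.transcript_id}")
    offset = 0
    for s, e in _cds_in_translation_order(tx):
        length = e - s + 1
        if cpos <= offset + length:
            k = cpos - offset
            return s + k - 1 if tx.strand == "+" else e - k + 1
        offset += length
    raise AssertionError("unreachable")


def cds_interval_to_genomic(tx: TranscriptModel, cds_start: int, cds_end: int
                            ) -> list[tuple[int, int]]:
    """Project a CDS range to the minimal list of genomic intervals.

    Returned sorted by genomic start; a range spanning an intron yields
    multiple intervals.
    """
    if not (1 <= cds_start <= cds_end <= tx.cds_length):
        raise ValueError(
            f"CDS range [{cds_start},{cds_end}] out of bounds for {tx.transcript_id}"
        )
    positions = sorted(cds_coord_to_genomic(tx, c) for c in range(cds_start, cds_end + 1))
    out = [(positions[0], positions[0])]
    for p in positions[1:]:
        if p == out[-1][1] + 1:
            out[-1] = (out[-1][0], p)
        else:
            out.append((p, p))
    return out


def variant_overlaps_cds(tx: TranscriptModel, v: Variant) -> bool:
    """True when the variant's REF span intersects the transcript CDS."""
    return any(v.pos <= e and v.end >= s for s, e in tx.cds)
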