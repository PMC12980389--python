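"""Shared fixtures: the worked single-exon toy and simulated bundles."""

import pytest

from haploproteo.model import Thresholds, TranscriptModel, Variant

# Single-exon plus-strand toy: CDS 4-21 of a 25 nt chromosome.
# Reference CDS "ATGAAACCCGGGTTTTAG" -> protein MKPGF.
TOY_CHR1 = "GGGATGAAACCCGGGTTTTAGGGGG"


@pytest.fixture
def toy_genome():
    return {"chr1": TOY_CHR1}


@pytest.fixture
def toy_tx():
    return TranscriptModel(
        transcript_id="T1", gene_id="G1", chrom="chr1", strand="+",
        exons=[(1, 25)], cds=[(4, 21)])


@pytest.fixture
def toy_variants():
    """Het V1 (cds 4, A>G, 1|0), hom V2 (cds 10, G>T), het V3 (cds 13,
    T>C, 0|1); hets share phase set 4."""
    return [
        Variant("chr1", 7, "A", "G", (1, 0), phased=True, phase_set=4,
                genotype_quality=40),
        Variant("chr1", 13, "G", "T", (1, 1), phased=False,
                genotype_quality=50),
        Variant("chr1", 16, "T", "C", (0, 1), phased=True, phase_set=4,
                genotype_quality=30),
    ]


@pytest.fixture
def toy_thresholds():
    """Thresholds with the CDS-length refilter relaxed for 5-codon toys."""
    return Thresholds(min_cds_nt=0)
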