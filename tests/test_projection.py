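"""Haplotype projection engine: application, translation, effects, labels."""

import pytest
from _oracle import projection_recovery

from haploproteo.model import Thresholds, TranscriptModel, Variant
from haploproteo.projection import (
    HaplotypeProtein,
    apply_variants_to_cds,
    assign_haplotype_labels,
    diff_string,
    map_variant_to_cds,
    project_transcript_haplotypes,
    translate_cds,
)

CDS = "ATGAAACCCGGGTTTTAG"


class TestTranslate:
    @pytest.mark.parametrize("nt,expected", [
        ("ATGAAACCCGGGTTTTAG", ("MKPGF", True, 6)),
        ("ATGGAACCCTGGTTTTAG", ("MEPWF", True, 6)),
        ("ATGAAA", ("MK", False, None)),
        ("ATGANA", ("MX", False, None)),
    ])
    def test_examples(self, nt, expected):
        assert translate_cds(nt) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate_cds("AT")


class TestApplyVariants:
    def _applied(self, toy_tx, variant):
        av = map_variant_to_cds(toy_tx, variant)
        assert av is not None
        return av

    def test_snv_on_carrying_haplotype(self, toy_tx):
        av = self._applied(toy_tx, Variant("chr1", 7, "A", "G", (1, 0),
                                           phased=True, phase_set=4))
        assert apply_variants_to_cds(CDS, [av], 1) == "ATGGAACCCGGGTTTTAG"
        assert apply_variants_to_cds(CDS, [av], 2) == CDS

    def test_deletion_shortens(self, toy_tx):
        av = self._applied(toy_tx, Variant("chr1", 7, "AA", "A", (1, 1)))
        out = apply_variants_to_cds(CDS, [av], 1)
        assert out == "ATGAACCCGGGTTTTAG" and len(out) == len(CDS) - 1

    def test_ref_mismatch_raises(self, toy_tx):
        av = self._applied(toy_tx, Variant("chr1", 7, "A", "G", (1, 0)))
        av.cds_ref = "C"
        with pytest.raises(ValueError, match="REF mismatch"):
            apply_variants_to_cds(CDS, [av], 1)

    def test_minus_strand_alleles_reverse_complemented(self):
        tx = TranscriptModel("Tm", "G", "chr1", "-", exons=[(1, 25)],
                             cds=[(4, 21)])
        av = map_variant_to_cds(tx, Variant("chr1", 21, "C", "T", (1, 1)))
        assert (av.cds_pos, av.cds_ref, av.cds_alt) == (1, "G", "A")


class TestProjectToy:
    def test_two_haplotypes(self, toy_genome, toy_tx, toy_variants,
                            toy_thresholds):
        out = project_transcript_haplotypes(
            toy_genome, toy_tx, toy_variants, toy_thresholds)
        by_hap = {p.haplotype_index: p for p in out}
        assert by_hap[1].aa_sequence == "MEPWF"
        assert by_hap[2].aa_sequence == "MKPWL"
        assert by_hap[1].diff_string == "K2E;G4W"
        assert not by_hap[1].flags.has_indel
        assert not by_hap[1].flags.frameshift
        # hom V2 applied on both; each het on exactly one
        assert len(by_hap[1].applied_variants) == 2
        assert len(by_hap[2].applied_variants) == 2

    def test_hom_only_collapses(self, toy_genome, toy_tx, toy_thresholds):
        v2 = Variant("chr1", 13, "G", "T", (1, 1))
        (p,) = project_transcript_haplotypes(
            toy_genome, toy_tx, [v2], toy_thresholds)
        assert p.haplotype_label == "HOM" and p.aa_sequence == "MKPWF"
        assert p.entry_id == "T1"

    def test_silent_snv_yields_reference_hom(self, toy_genome, toy_tx,
                                             toy_thresholds):
        # cds 6 A>G: AAA->AAG, both lysine
        v = Variant("chr1", 9, "A", "G", (1, 1))
        (p,) = project_transcript_haplotypes(
            toy_genome, toy_tx, [v], toy_thresholds)
        assert p.haplotype_label == "HOM"
        assert p.aa_sequence == "MKPGF" and p.applied_variants == []

    def test_zero_variants_project_to_reference(self, toy_genome, toy_tx,
                                                toy_thresholds):
        (p,) = project_transcript_haplotypes(toy_genome, toy_tx, [],
                                             toy_thresholds)
        assert p.aa_sequence == "MKPGF" and p.haplotype_label == "HOM"

    def test_unphased_het_rejected(self, toy_genome, toy_tx, toy_thresholds):
        v = Variant("chr1", 7, "A", "G", (0, 1), phased=False)
        with pytest.raises(ValueError, match="unphased"):
            project_transcript_haplotypes(toy_genome, toy_tx, [v],
                                          toy_thresholds)


class TestEffectFlags:
    def test_frameshift_deletion(self, toy_genome, toy_tx, toy_thresholds):
        v = Variant("chr1", 10, "CC", "C", (1, 1))
        (p,) = project_transcript_haplotypes(toy_genome, toy_tx, [v],
                                             toy_thresholds)
        assert p.flags.has_indel and p.flags.frameshift
        assert not p.flags.resolved_frameshift

    def test_resolved_frameshift(self, toy_genome, toy_tx, toy_thresholds):
        vs = [Variant("chr1", 7, "AA", "A", (1, 1)),
              Variant("chr1", 13, "G", "GA", (1, 1))]
        (p,) = project_transcript_haplotypes(toy_genome, toy_tx, vs,
                                             toy_thresholds)
        assert p.flags.resolved_frameshift and not p.flags.frameshift

    def test_changed_start_flagged_but_emitted(self, toy_genome, toy_tx,
                                               toy_thresholds):
        v = Variant("chr1", 5, "T", "C", (1, 1))  # ATG -> ACG
        (p,) = project_transcript_haplotypes(toy_genome, toy_tx, [v],
                                             toy_thresholds)
        assert p.flags.changed_start and p.aa_sequence[0] == "T"

    def test_lost_stop_extends_into_utr3(self, toy_thresholds):
        # CDS 4-21 with UTR3 "GAATAG...": lost stop reads GAA (E) then TAG
        genome = {"chr1": "GGGATGAAACCCGGGTTTTAGGAATAGGG"}
        tx = TranscriptModel("T1", "G1", "chr1", "+", exons=[(1, 29)],
                             cds=[(4, 21)])
        v = Variant("chr1", 19, "T", "C", (1, 1))  # TAG -> CAG (Q)
        (p,) = project_transcript_haplotypes(genome, tx, [v], toy_thresholds)
        assert p.aa_sequence == "MKPGFQE"
        assert p.flags.changed_stop and not p.flags.truncated

    def test_lost_stop_without_downstream_terminator_truncates(
            self, toy_genome, toy_tx, toy_thresholds):
        v = Variant("chr1", 19, "T", "C", (1, 1))
        (p,) = project_transcript_haplotypes(toy_genome, toy_tx, [v],
                                             toy_thresholds)
        assert p.flags.changed_stop and p.flags.truncated


class TestDiffString:
    def test_substitutions(self):
        assert diff_string("MKPGF", "MEPWF") == "K2E;G4W"
        assert diff_string("MKPGF", "MKPGF") == ""

    def test_deletion_and_insertion(self):
        assert diff_string("MKPGF", "MKGF") == "del3P"
        assert diff_string("MKGF", "MKPGF") == "ins3P"


def _hp(tid, hap_index, variants_with_genotype):
    """Het entry stub carrying the given (variant, genotype) pairs."""
    from haploproteo.projection import AppliedVariant
    applied = []
    for v in variants_with_genotype:
        if hap_index in v.haplotypes_carrying_alt() or v.is_het:
            applied.append(AppliedVariant(
                variant=v, cds_pos=1, cds_ref=v.ref_allele,
                cds_alt=v.alt_allele,
                haplotypes_carrying=v.haplotypes_carrying_alt()))
    return HaplotypeProtein(
        transcript_id=tid, gene_id="G1",
        haplotype_label="A" if hap_index == 1 else "B",
        haplotype_index=hap_index, aa_sequence="M" * 10,
        applied_variants=applied)


class TestLabelAssignment:
    def test_single_isoform_default(self):
        v = Variant("chr1", 10, "A", "G", (1, 0), phased=True, phase_set=1)
        pair = [_hp("T1", 1, [v]), _hp("T1", 2, [v])]
        assign_haplotype_labels(pair)
        assert [p.haplotype_label for p in pair] == ["A", "B"]

    def test_shared_het_with_opposite_order_flips(self):
        # same site, opposite haplotype order in the second isoform's
        # applied record (per-isoform phasing discrepancy)
        v_fwd = Variant("chr1", 10, "A", "G", (1, 0), phased=True, phase_set=1)
        v_rev = Variant("chr1", 10, "A", "G", (0, 1), phased=True, phase_set=1)
        entries = [_hp("T1", 1, [v_fwd]), _hp("T1", 2, [v_fwd]),
                   _hp("T2", 1, [v_rev]), _hp("T2", 2, [v_rev])]
        assign_haplotype_labels(entries)
        by = {(e.transcript_id, e.haplotype_index): e.haplotype_label
              for e in entries}
        assert by[("T1", 1)] == "A"          # alt on hap1 -> letter A
        assert by[("T2", 2)] == "A"          # alt on hap2 -> flipped to A
        assert by[("T2", 1)] == "B"

    def test_disjoint_het_sets_default(self):
        v1 = Variant("chr1", 10, "A", "G", (1, 0), phased=True, phase_set=1)
        v2 = Variant("chr1", 90, "C", "T", (0, 1), phased=True, phase_set=2)
        entries = [_hp("T1", 1, [v1]), _hp("T1", 2, [v1]),
                   _hp("T2", 1, [v2]), _hp("T2", 2, [v2])]
        assign_haplotype_labels(entries)
        assert all(e.haplotype_label == ("A" if e.haplotype_index == 1 else "B")
                   for e in entries)

    def test_invariant_to_input_order(self):
        v_fwd = Variant("chr1", 10, "A", "G", (1, 0), phased=True, phase_set=1)
        v_rev = Variant("chr1", 10, "A", "G", (0, 1), phased=True, phase_set=1)
        def build():
            return [_hp("T1", 1, [v_fwd]), _hp("T1", 2, [v_fwd]),
                    _hp("T2", 1, [v_rev]), _hp("T2", 2, [v_rev])]
        a, b = build(), list(reversed(build()))
        assign_haplotype_labels(a)
        assign_haplotype_labels(b)
        la = {(e.transcript_id, e.haplotype_index): e.haplotype_label for e in a}
        lb = {(e.transcript_id, e.haplotype_index): e.haplotype_label for e in b}
        assert la == lb


class TestGroundTruthRecovery:
    def test_genome_edit_oracle_small(self):
        ok, total = projection_recovery(seeds=range(4), n_genes=10)
        assert ok == total

    def test_het_only_haplotypes_differ(self):
        from haploproteo import simulate as sim
        from haploproteo.pipeline import project_all
        genome, txs = sim.simulate_reference(11, n_genes=8)
        variants, _ = sim.simulate_phased_variants(
            12, genome, txs, n_het_snv=2, n_hom_snv=0)
        for p1 in project_all(genome, txs, variants, Thresholds()):
            for p2 in project_all(genome, txs, variants, Thresholds()):
                if (p1.transcript_id == p2.transcript_id
                        and p1.haplotype_index == 1 and p2.haplotype_index == 2):
                    assert p1.aa_sequence != p2.aa_sequence
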