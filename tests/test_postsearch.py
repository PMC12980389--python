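"""Post-search annotation: PSM filtering, classification, variant
identification, protein/gene inference, genome back-projection."""

import random

import pytest

from haploproteo.database import ProteinDatabaseEntry
from haploproteo.model import Thresholds, TranscriptModel, Variant
from haploproteo.postsearch import (
    DatabaseIndex,
    PeptideSpectrumMatch,
    assign_peptide_haplotype,
    build_annotation_records,
    classify_peptide,
    filter_psms,
    identify_direct_variants,
    identify_genes,
    infer_linked_variants,
    infer_protein_groups,
    project_peptide_to_genome,
    strip_modifications,
)
from haploproteo.projection import AppliedVariant, HaplotypeProtein

TH = Thresholds()

# --- hand-built toy database -------------------------------------------------
# T1 (gene G1) carries het V1 (residue 6: E on A / G on B), hom V2
# (residue 11: W on both), het V3 (residue 14: L on A / I on B); V1 and V3
# share phase set 100 with alt on haplotype 1.  T2 (gene G2) is an
# unchanged reference isoform; N1 (gene G3) is a novel-splice product.
V1 = Variant("chr1", 50, "A", "G", (1, 0), phased=True, phase_set=100,
             genotype_quality=60)
V2 = Variant("chr1", 65, "T", "G", (1, 1), genotype_quality=60)
V3 = Variant("chr1", 74, "C", "T", (1, 0), phased=True, phase_set=100,
             genotype_quality=60)

SEQ_A = "MTTTKEAAAKWAALDDDK"
SEQ_B = "MTTTKGAAAKWAAIDDDK"
REF_T1 = "MTTTKGAAAKFAAIDDDK"  # ref alleles at V1/V3, F at the hom site
REF_T2 = "MPPPPPGGGGGWPPPK"
SEQ_N1 = "MYYYSPLICEDSEQYYYK"


def _av(v, prot_pos):
    return AppliedVariant(v, 3 * prot_pos - 2, v.ref_allele, v.alt_allele,
                          v.haplotypes_carrying_alt(),
                          protein_start=prot_pos, protein_end=prot_pos)


def make_db():
    hp_a = HaplotypeProtein("T1", "G1", "A", 1, SEQ_A,
                            applied_variants=[_av(V1, 6), _av(V2, 11),
                                              _av(V3, 14)],
                            phase_set=100)
    hp_b = HaplotypeProtein("T1", "G1", "B", 2, SEQ_B,
                            applied_variants=[_av(V2, 11)], phase_set=100)
    hp_n = HaplotypeProtein("N1", "G3", "HOM", None, SEQ_N1,
                            is_novel_splice=True)
    entries = [
        ProteinDatabaseEntry("T1.A", SEQ_A, entry_class="variant"),
        ProteinDatabaseEntry("T1.B", SEQ_B, entry_class="variant"),
        ProteinDatabaseEntry("T2", REF_T2, entry_class="reference"),
        ProteinDatabaseEntry("N1", SEQ_N1, entry_class="novel_splice"),
        ProteinDatabaseEntry("CON_1", "MCCCCCCKDDDDDDR",
                             entry_class="contaminant"),
        ProteinDatabaseEntry("XXX_T2", REF_T2[::-1], entry_class="decoy"),
    ]
    return DatabaseIndex(entries, [hp_a, hp_b, hp_n],
                         reference_proteome=[REF_T1, REF_T2]), [hp_a, hp_b, hp_n]


class TestFilterPsms:
    def test_q_value_and_decoy_rules(self):
        db, _ = make_db()
        psms = [
            PeptideSpectrumMatch("EAAAK", 0.005, ["T1.A"]),
            PeptideSpectrumMatch("MTTTK", 0.02, ["T1.A", "T1.B"]),
            PeptideSpectrumMatch("KPPPW", 0.001, ["XXX_T2"]),
            PeptideSpectrumMatch("CCCCK", 0.001, ["CON_1"]),
        ]
        assert filter_psms(psms, db, TH) == {"EAAAK"}

    def test_unresolvable_id_raises(self):
        db, _ = make_db()
        with pytest.raises(ValueError, match="unresolvable"):
            filter_psms([PeptideSpectrumMatch("EAAAK", 0.001, ["NOPE"])],
                        db, TH)

    def test_modifications_stripped(self):
        assert strip_modifications("EAAM[+15.995]AK") == "EAAMAK"
        assert strip_modifications("C(cam)PEP") == "CPEP"


class TestClassification:
    def test_reference_even_for_replaced_isoform_region(self):
        db, _ = make_db()
        # substring of the reference T1 protein, which is not a db entry
        assert classify_peptide("MTTTK", db) == "reference"
        assert classify_peptide("WPPPK", db) == "reference"

    def test_variant_peptide(self):
        db, _ = make_db()
        assert classify_peptide("EAAAK", db) == "variant"

    def test_splice_peptide(self):
        db, _ = make_db()
        assert classify_peptide("SPLICEDSEQ", db) == "splice"

    def test_reference_precedence_over_other_matches(self):
        db, _ = make_db()
        # IDDDK occurs in variant-class T1.B but also in the reference T1
        # protein, so the reference category wins
        assert classify_peptide("IDDDK", db) == "reference"


class TestHaplotypeAssignment:
    def test_single_haplotype_match(self):
        db, _ = make_db()
        assert assign_peptide_haplotype("EAAAK", db) == "A"

    def test_both_haplotypes_homozygous(self):
        db, _ = make_db()
        assert assign_peptide_haplotype("MTTTK", db) == "homozygous"

    def test_multiple_isoforms_homozygous(self):
        entries = [ProteinDatabaseEntry("T1.A", "MWWWKAAAAK",
                                        entry_class="variant"),
                   ProteinDatabaseEntry("T7.B", "MCCCKAAAAK",
                                        entry_class="variant")]
        hps = [HaplotypeProtein("T1", "G1", "A", 1, "MWWWKAAAAK"),
               HaplotypeProtein("T7", "G7", "B", 2, "MCCCKAAAAK")]
        db = DatabaseIndex(entries, hps)
        assert assign_peptide_haplotype("AAAAK", db) == "homozygous"


class TestDirectAndLinked:
    def test_direct_requires_span_and_uniqueness(self):
        db, hps = make_db()
        accepted = {"EAAAK", "MTTTK"}
        direct = identify_direct_variants(accepted, db)
        assert [(vi.variant.key, vi.zygosity) for vi in direct] == \
            [(V1.key, "heterozygous")]

    def test_downstream_peptide_not_direct(self):
        db, _ = make_db()
        assert identify_direct_variants({"MTTTK"}, db) == []

    def test_reference_shared_peptide_not_direct(self):
        db, _ = make_db()
        # WAA1 covers hom V2 at residue 11 but occurs in both haplotypes,
        # which both carry it -> direct; AAK occurs in reference too -> not
        direct = identify_direct_variants({"KWAAI"}, db)
        # KWAAI covers V2 (11) in T1.B only; T1.A lacks KWAAI; unique
        assert [vi.variant.key for vi in direct] == [V2.key]

    def test_linked_het_and_hom(self):
        db, hps = make_db()
        direct = identify_direct_variants({"EAAAK"}, db)
        linked = infer_linked_variants(direct, hps)
        got = {(vi.variant.key, vi.mode, vi.zygosity) for vi in linked}
        assert (V3.key, "linked", "heterozygous") in got  # same phase block
        assert (V2.key, "linked", "homozygous") in got    # same entry
        assert not {vi.variant.key for vi in linked} & \
            {vi.variant.key for vi in direct}

    def test_no_direct_no_linked(self):
        _, hps = make_db()
        assert infer_linked_variants([], hps) == []


class TestProteinGroups:
    @staticmethod
    def _db(sets):
        # one 6-letter token per peptide, 'W' as separator: containment
        # in a sequence then equals set membership
        tokens = {}
        rng = random.Random(42)
        for peps in sets.values():
            for p in peps:
                if p not in tokens:
                    tokens[p] = "".join(rng.choice("ACDEFGHILMNQSTVY")
                                        for _ in range(6))
        entries = [ProteinDatabaseEntry(
            name, "W" + "W".join(tokens[p] for p in sorted(peps)) + "W")
            for name, peps in sets.items()]
        return DatabaseIndex(entries), tokens

    def test_greedy_with_tie_break(self):
        db, tokens = self._db({"A": {"p1", "p2"}, "B": {"p2", "p3"},
                               "C": {"p3"}})
        accepted = {tokens[p] for p in ("p1", "p2", "p3")}
        groups = infer_protein_groups(accepted, db)
        assert [g.member_entry_ids for g in groups] == [["A"], ["B"]]

    def test_identical_sets_merged(self):
        db, tokens = self._db({"A": {"p1", "p2"}, "A2": {"p1", "p2"}})
        groups = infer_protein_groups({tokens["p1"], tokens["p2"]}, db)
        assert [g.member_entry_ids for g in groups] == [["A", "A2"]]

    def test_single_cover(self):
        db, tokens = self._db({"A": {"p1", "p2", "p3"}, "B": {"p2"}})
        groups = infer_protein_groups(set(tokens.values()), db)
        assert [g.member_entry_ids for g in groups] == [["A"]]

    @pytest.mark.parametrize("seed", range(10))
    def test_cover_valid_and_greedy_invariant(self, seed):
        rng = random.Random(seed)
        n_prot = rng.randrange(2, 13)
        n_pep = rng.randrange(n_prot, 41)
        peps = [f"p{i}" for i in range(n_pep)]
        sets = {}
        for i in range(n_prot):
            k = rng.randrange(1, n_pep + 1)
            sets[f"P{i:02d}"] = set(rng.sample(peps, k))
        covered_peps = set().union(*sets.values())
        db, tokens = self._db(sets)
        accepted = {tokens[p] for p in covered_peps}
        groups = infer_protein_groups(accepted, db)
        union = set().union(*(g.supporting_peptides for g in groups))
        assert union == accepted
        # greedy invariant: each chosen group had maximal marginal coverage
        candidate_sets = {}
        for name, ps in sets.items():
            candidate_sets.setdefault(frozenset(tokens[p] for p in ps),
                                      []).append(name)
        done = set()
        for g in groups:
            best = max(len(s - done) for s in candidate_sets)
            assert len(g.supporting_peptides - done) == best
            done |= g.supporting_peptides


class TestGenes:
    def test_gene_identified_from_haplotype_pair(self):
        groups = [type("G", (), {"member_entry_ids": ["T1.A", "T1.B"]})()]
        assert identify_genes(groups, {"T1.A": {"G1"}, "T1.B": {"G1"}}) == {"G1"}

    def test_multi_gene_group_identifies_nothing(self):
        groups = [type("G", (), {"member_entry_ids": ["T1", "T7"]})()]
        assert identify_genes(groups, {"T1": {"G1"}, "T7": {"G7"}}) == set()

    def test_empty(self):
        assert identify_genes([], {}) == set()


class TestGenomeProjection:
    def test_plus_strand_single_block(self, toy_tx):
        entry = ProteinDatabaseEntry("T1", "MKPGF")
        hp = HaplotypeProtein("T1", "G1", "HOM", None, "MKPGF")
        assert project_peptide_to_genome("KPG", entry, toy_tx, hp) == [(7, 15)]

    def test_junction_spanning_peptide_two_blocks(self):
        tx = TranscriptModel("T", "G", "c", "+", exons=[(1, 100)],
                             cds=[(4, 12), (31, 39)])
        # protein residues 1..6 over an 18 nt CDS split 9+9
        entry = ProteinDatabaseEntry("T", "MKPGFW")
        hp = HaplotypeProtein("T", "G", "HOM", None, "MKPGFW")
        ivs = project_peptide_to_genome("PGFW", entry, tx, hp)
        assert ivs == [(10, 12), (31, 39)]

    def test_indel_offset_inverted(self, toy_tx):
        # het 1-nt deletion at CDS 7 shifts downstream residues by one
        v = Variant("chr1", 9, "AC", "A", (1, 0), phased=True, phase_set=9)
        av = AppliedVariant(v, 6, "AC", "A", frozenset({1}),
                            protein_start=2, protein_end=2)
        hp = HaplotypeProtein("T1", "G1", "A", 1, "MKPGV",
                              applied_variants=[av])
        entry = ProteinDatabaseEntry("T1.A", "MKPGV", entry_class="variant")
        # residues 3..4 sit at edited nt 7..12 = reference CDS 8..13
        assert project_peptide_to_genome("PG", entry, toy_tx, hp) == [(11, 16)]

    def test_missing_peptide_raises(self, toy_tx):
        entry = ProteinDatabaseEntry("T1", "MKPGF")
        hp = HaplotypeProtein("T1", "G1", "HOM", None, "MKPGF")
        with pytest.raises(ValueError, match="not found"):
            project_peptide_to_genome("WWW", entry, toy_tx, hp)


class TestAnnotationRecords:
    def test_counts_and_flags(self):
        _, hps = make_db()
        df = build_annotation_records(hps).set_index("protein_id")
        row = df.loc["T1.A"]
        assert (row.n_het_snv, row.n_hom_snv, row.n_het_indel,
                row.n_hom_indel) == (2, 1, 0, 0)
        assert df.loc["T1.B"].n_hom_snv == 1 and df.loc["T1.B"].n_het_snv == 0
        assert df.loc["N1"].is_novel_splice
        assert df.loc["N1"].variants == "" and df.loc["N1"].n_hom_snv == 0
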