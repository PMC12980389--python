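"""Independent oracles shared between unit and acceptance tests."""

from haploproteo import simulate as sim
from haploproteo.model import Thresholds, spliced_cds_sequence
from haploproteo.pipeline import project_all
from haploproteo.projection import translate_cds


def projection_recovery(seeds, n_genes=10, n_het_snv=2, n_hom_snv=1,
                        n_het_indel=1, n_hom_indel=1, th=None):
    """(n_recovered, n_total) transcripts whose projected haplotype proteins
    equal the translation of independently genome-edited truth sequences.

    The truth path applies variants in genome space and re-extracts the
    spliced CDS; the tested path edits in CDS space. A haplotype whose
    truth protein falls below the minimum codon length is expected absent.
    """
    th = th or Thresholds()
    min_codons = th.min_cds_nt // 3
    n_ok = n_total = 0
    for seed in seeds:
        genome, txs = sim.simulate_reference(seed, n_genes=n_genes)
        variants, truth = sim.simulate_phased_variants(
            seed + 10_000, genome, txs, n_het_snv=n_het_snv,
            n_hom_snv=n_hom_snv, n_het_indel=n_het_indel,
            n_hom_indel=n_hom_indel)
        products = project_all(genome, txs, variants, th)
        for tx in txs:
            n_total += 1
            e1, e2 = truth.expected_proteins[tx.transcript_id]
            expected = {h: aa for h, aa in ((1, e1), (2, e2))
                        if len(aa) >= min_codons}
            mine = [p for p in products if p.transcript_id == tx.transcript_id]
            got = {}
            for p in mine:
                if p.haplotype_label == "HOM":
                    got[1] = got[2] = p.aa_sequence
                else:
                    got[p.haplotype_index] = p.aa_sequence
            if mine:
                ok = got == expected
            else:
                # no non-silent variation: truth must equal the reference
                ref_aa = translate_cds(spliced_cds_sequence(genome, tx))[0]
                ok = all(aa == ref_aa for aa in expected.values())
            n_ok += ok
    return n_ok, n_total


def brute_force_digest(seq, max_missed, min_len, max_len):
    """Enumerate all substrings and keep valid tryptic fragments."""
    def is_cut(k):  # cleavage between k-1 and k (0-based)
        return 0 < k < len(seq) and seq[k - 1] in "KR" and seq[k] != "P"
    out = set()
    n = len(seq)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if i != 0 and not is_cut(i):
                continue
            if j != n and not is_cut(j):
                continue
            missed = sum(is_cut(k) for k in range(i + 1, j))
            if missed <= max_missed and min_len <= j - i <= max_len:
                out.add(seq[i:j])
    return out
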