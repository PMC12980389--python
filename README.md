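# haploproteo

Haplotype-resolved, sample-specific proteogenomics: build an allele-resolved
protein search database from a genome, CDS annotation and phased variants;
annotate the resulting peptide-spectrum matches; and evaluate phasing
quality at coding-sequence resolution.

Standard proteomics searches use one reference proteome and therefore miss
the proteins a particular sample actually expresses: allele-specific
products of heterozygous variants, homozygous variant isoforms, and novel
splice products. Given phased variants (e.g. from long-read RNA-seq
phasing), each transcript's CDS can be projected onto both haplotypes,
translated, and searched as two allele-specific proteins (`.A` / `.B`).
After the search, phasing pays off twice: a *unique* peptide spanning an
altered residue identifies its variant **directly**, and every other
variant on the same phase block (or co-resident on the same protein, for
homozygous variants) is identified **by linkage** without any peptide
covering it.

The package is aimed at proteogenomics method developers and pipeline
builders. It implements the bespoke computation between the standard
ecosystem tools — it consumes FASTA/GTF/phased-VCF and a search engine's
PSM table, and does not run aligners, callers, phasers or search engines.

## What it computes

- **Variant post-processing** — GQ ≥ 5 and biallelic filtering, then the
  CDS phase-contiguity guarantee: after the chain, every CDS contains
  heterozygous variants from at most one phase block (conflicting hets
  removed; lone hets arbitrarily phased with `PS = position`).
- **Haplotype projection** — strand-aware CDS editing per haplotype
  (SNVs, in-frame and frameshift indels), translation with stop-loss
  extension into the 3' UTR, silent-variant handling, effect flags
  (indel / frameshift / resolved frameshift / changed stop / changed
  start / truncated) and a residue-level diff string such as `K2E;G4W`.
- **Database assembly** — variant-bearing isoforms replaced by haplotype
  products, sequence deduplication with accession tracking, contaminant
  concatenation, and reversed-sequence decoys (`XXX_`) whose tryptic
  peptides are shuffled out of collision with the target universe
  (trypsin, ≤ 2 missed cleavages, peptide length 5–100, ≤ 100 iterations).
- **Post-search annotation** — q < 0.01 PSM filtering; peptide classes
  (reference / variant / splice / variant_splice); peptide haplotype
  assignment; direct and linked variant identification; greedy set-cover
  protein inference; the gene rule (a gene is identified iff some protein
  group maps entirely to it); BED12 browser tracks by back-projecting
  peptides through the edits to genome coordinates.
- **Phasing evaluation** — switch error rate over consecutive shared het
  pairs (rate = switches / assessed pairs, flip-invariant), phased-variant
  counts, and fully-phased region fractions at CDS / transcript / gene
  level, stratifiable by coverage and SNV-only vs SNV+indel.
- **Synthetic fixtures** — seeded generators for genome/GTF/VCF/PSM inputs
  whose ground truth (haplotype sequences built by independent genome-space
  editing, planted switch errors) makes every stage testable end to end.

## Worked example

```python
from haploproteo import simulate as sim
from haploproteo.model import write_genome_fasta, write_gtf, write_vcf, Thresholds
from haploproteo.database import build_database
from haploproteo.pipeline import (RunConfig, run_pipeline, project_all,
                                  reference_proteome)

genome, txs = sim.simulate_reference(seed=1, n_genes=8)
variants, truth = sim.simulate_phased_variants(
    2, genome, txs, n_het_snv=2, n_hom_snv=1, n_het_indel=1)
write_genome_fasta(genome, "genome.fasta")
write_gtf(txs, "annotation.gtf")
write_vcf(variants, "variants.vcf", contigs={c: len(s) for c, s in genome.items()})

prots = project_all(genome, txs, variants, Thresholds())
db = build_database(reference_proteome(genome, txs), prots, seed=3)
sim.simulate_search_results(4, db, coverage_fraction=0.8).to_csv(
    "psms.tsv", sep="\t", index=False)

run_pipeline(RunConfig(genome="genome.fasta", gtf="annotation.gtf",
                       vcf="variants.vcf", psms="psms.tsv",
                       out_dir="out", seed=5))
```

The run writes `out/database.fasta` plus sidecar, annotation tables and a
checksum manifest. On this seed the protein annotation begins:

```
protein_id haplotype  n_het_snv  n_hom_snv  n_het_indel    diff_string  frameshift
    T001.B         B          1          1            0       A7T;Y23F       False
    T002.A         A          2          1            0 K17Q;S27T;P49S       False
    T002.B         B          0          1            1    ins34E;P49S       False
```

i.e. haplotype B of transcript T001 carries one heterozygous and one
homozygous SNV changing residues 7 and 23; haplotype B of T002 carries a
one-residue insertion after position 33 plus a shared homozygous
substitution. The variant identification table summarizes to:

```
mode    zygosity
direct  heterozygous    13
        homozygous       4
linked  heterozygous     2
        homozygous       1
```

— 17 variants confirmed by unique spanning peptides, and 3 more inferred
purely from phase/protein co-residence. Of the 150 accepted peptides, 83
were reference and 67 variant peptides, and all 8 simulated genes were
identified.

The same flow is available from the shell:

```
haploproteo simulate --seed 1 --n-genes 8 --out-dir fixtures
haploproteo build-db --genome fixtures/genome.fasta \
    --gtf fixtures/annotation.gtf --vcf fixtures/variants.vcf --out-dir out
haploproteo annotate ... --psms psms.tsv --out-dir out
haploproteo phase-eval --truth truth.vcf --test test.vcf --gtf a.gtf --out metrics.tsv
```

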