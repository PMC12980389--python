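# Methods

`haploproteo` implements the bespoke computational core of a sample-specific,
haplotype-resolved proteogenomics workflow. The surrounding ecosystem tools —
aligner, variant caller, read-based phaser, transcript discovery, and the
search engine — are deliberately not run here; the package consumes their
standard-format outputs (FASTA, GTF, phased VCF, PSM tables) and produces the
search database and all post-search annotation.

## Model and procedure

**Variant model.** Variants are single-sample, biallelic sites with genotype
`(a1, a2)` over allele indices (0 = ref, 1 = alt). Phased heterozygous
genotypes assign alleles to haplotypes 1 and 2 within a phase set (PS tag): a
maximal block of hets whose relative assignment is jointly determined.
Multi-allelic records are flagged at read time and removed by the filter, as
is any variant with genotype quality below `min_gq` (default 5).

**CDS phase contiguity.** Haplotype projection of a transcript is well
defined only when all heterozygous variants in its CDS belong to one phase
block. The post-processing chain enforces this: for every CDS whose hets
span more than one phase set (or include an unphased het), all hets in that
CDS are removed; a het failing in any overlapping CDS is removed globally.
"Belongs to one phase block" is the operative reading of block/CDS
contiguity — a block's physical span is defined only by its member variants,
so an endpoint-coverage reading would discard nearly everything. Removal
(rather than demotion to unphased) is used because an unphased het cannot be
placed on a haplotype downstream. Conversely, an unphased het that is the
*only* het in every CDS it touches is arbitrarily phased (haplotype 1 = alt)
with a fresh phase set equal to its genomic position — phasing is genuinely
arbitrary for a lone het, and the position makes the identifier
deterministic and collision-free.

**Projection.** For each transcript the spliced CDS (stop codon included,
minus-strand intervals reverse-complemented and taken highest-coordinate
first) is edited per haplotype: variants are mapped into CDS coordinates
(alleles strand-transformed), checked against the reference sequence, and
substituted in descending CDS position so upstream coordinates stay valid.
Edits spanning a CDS/intron boundary have no defined projection and are
skipped with a warning. Translation uses the standard genetic code; codons
containing N yield `X`. If an edit removes the terminator, translation
continues into the transcript's downstream exonic sequence until the next
in-frame stop; if none exists the product is flagged truncated. A variant is
*silent* when applying it alone leaves the protein unchanged; silent
variants are still substituted into the haplotype sequence (a third-base
substitution matters downstream of a frameshift) but are excluded from the
applied-variant annotation, and a transcript is only considered
variant-bearing if it has at least one non-silent variant. Products shorter
than `min_cds_nt / 3` codons (default 33) are dropped, mirroring the
post-projection length refilter. Identical haplotype products collapse into
a single unsuffixed `HOM` entry; heterozygous products get `.A` / `.B`
suffixes.

**Effect flags.** Scanning edits left to right with the cumulative length
offset: a final offset not divisible by 3 is a *frameshift*; an offset
non-zero mod 3 mid-scan that ends divisible by 3 is a *resolved frameshift*.
The stop is *changed* when the terminator is not the final codon of the
edited CDS (premature, lost, or pushed into the 3' UTR); *truncated* means
premature or absent. A changed start codon is flagged but the product is
still emitted translating from the annotated start — altered start handling
is out of scope and such events are rare in practice. The diff string lists
length-preserving changes as `<ref><pos><alt>` (`K2E;G4W`); when lengths
differ, a minimal edit-distance alignment (edlib) is rendered as
substitutions plus `del<pos><residues>` / `ins<pos><residues>` with 1-based
reference positions.

**A/B label reconciliation.** Within a gene, transcripts are visited in
lexicographic order; the first keeps haplotype 1 = A, and each later isoform
is oriented so that the leftmost het shared with an already-labeled isoform
keeps its alt allele on the same letter. Labels are assigned per isoform
without global back-tracking, so conflicting per-isoform phasings can in
principle produce discordant labels; with a single consistent phased VCF
the result is globally consistent and independent of input order.

**Database.** Reference isoforms with at least one non-silent variant are
replaced by their haplotype products (class `variant`); novel-splice
products are appended whether or not they carry variants. Deduplication
keeps one entry per distinct sequence, tracking all member accessions, with
the lexicographically smallest member as entry id; on a class conflict the
priority is reference > variant > novel_splice > contaminant, matching the
reference-first peptide classification. Contaminants are concatenated
*before* decoy generation so they receive decoys too. Decoys (prefix
`XXX_`) are whole-sequence reversals whose tryptic peptides colliding with
the target peptide universe are shuffled in place by a seeded RNG for up to
`max_decoy_iterations` (default 100) rounds; residual collisions are logged,
never silent. Decoys are generated from the deduplicated set (no duplicate
decoys). I and L are distinct residues in collision checks. Digestion
cleaves after K/R except before P, with up to 2 missed cleavages and
peptide lengths 5–100 (pyteomics' cleavage engine with this exact rule).

**Post-search annotation.** Accepted peptides have q-value < 0.01 and at
least one non-decoy, non-contaminant match; modification annotations are
stripped before matching. Classification is reference-first: any substring
of the *reference proteome* (including isoforms replaced in the database)
is a reference peptide; otherwise the explaining entry classes decide
(variant / splice / variant_splice). Peptides explained only by
variant-class entries but not overlapping an applied-variant span (e.g.
frameshift tails) are still categorized `variant`. A peptide is assigned
haplotype A or B only when it matches exactly one single-haplotype product;
all other cases are "homozygous".

A variant is identified *directly* when an accepted peptide occurs in an
entry carrying it, covers the full altered residue span (indels require one
flanking residue on each side, clamped at protein termini), and occurs in
no entry lacking the variant (sequence-level uniqueness). *Linked*
heterozygous identifications share a phase block with a directly identified
het; linked homozygous identifications reside on a haplotype protein that
carries a direct variant — homozygous variants have no phase block, so
co-residence on the protein is the linkage unit. Direct and linked sets are
disjoint by construction.

Protein inference is a greedy set cover: entries with identical
accepted-peptide sets merge into candidate groups; the loop repeatedly
picks the group covering the most uncovered peptides (ties broken by the
lexicographically smallest member id — tie-breaking is lexicographic
throughout the package) until all accepted peptides are covered. A gene is
identified iff some protein group's members (haplotype suffixes ignored)
all belong to it.

Browser-track back-projection converts a peptide's residue span to
edited-CDS nucleotides, inverts the applied indel offsets back to reference
CDS coordinates (positions inside an inserted segment clamp to the anchor),
and projects through the exon structure; junction-spanning peptides yield
blocked BED12 records.

**Phasing evaluation.** The switch error rate is the fraction of
consecutive shared-het pairs whose relative haplotype orientation disagrees
with truth, pooled over blocks. Pairs are assessed only when both sites
share a phase set in the test *and* the truth (relative orientation across
blocks is undefined), which makes the rate invariant under global flips and
zero for truth-vs-truth. Sites with discordant zygosity are excluded and
logged. Completeness reports phased/total het counts and fully-phased
region fractions at CDS (per-isoform CDS union), transcript (exon union)
and gene (pooled CDS of all isoforms) level; a region is fully phased when
its hets form one phase block, and regions with 0 or 1 het count as fully
phased. Because the denominator is ambiguous, both the all-regions fraction
and the fraction over het-containing regions are reported. Metrics can be
stratified by minimum site coverage and by SNV-only vs SNV+indel.

## Synthetic study conditions

The fixture generator emulates the inputs the pipeline expects, at desk
scale, with full ground truth:

- `simulate_reference`: multi-exon transcripts (default 3 exons) on
  alternating strands, CDS lengths 150–300 nt (multiples of 3, ATG start,
  terminator end), 40 nt UTRs, 50 nt introns, up to 5 genes per chromosome.
- `simulate_phased_variants`: per transcript, by default 2 het SNVs, 1 hom
  SNV and optionally het/hom indels of 1–6 nt (both in-frame and
  frameshifting), planted inside the CDS away from start/stop codons and
  exon boundaries, with non-overlapping spans. Hets form one phase block
  per transcript (or two under `fragmented`, to exercise the completeness
  filter). Truth haplotype sequences are built by editing the *genome*
  and re-extracting the spliced CDS — a path independent of the CDS-space
  projection engine — and truth proteins are translated with Biopython.
- `plant_switch_errors` flips block suffixes at chosen pair boundaries,
  recording exactly how many orientation changes were planted.
- `simulate_search_results` emits the full (or sampled) target tryptic
  peptide universe at q < 0.005, plus optional decoy-only and
  above-threshold noise rows. The q-value model is a crude two-component
  mixture with no claim of realism; it exists to exercise the filter.

What passing these conditions does *not* show: performance on real spectra
(no missing peptides due to ionization/detectability, no PTMs, no chimeric
spectra), real phasing error structure, splice-isoform discovery, or
genome-scale runtimes. The generators produce clean, well-spaced,
CDS-contained variants; real data contain boundary-spanning indels (skipped
with a warning here) and multi-transcript overlap structures richer than
the simulated one-isoform-per-gene default.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (GTF/VCF convention); BED
  output is 0-based half-open.
- All randomness (generators, decoy shuffling, PSM sampling) flows through
  explicit seeds; reruns are byte-identical, and the pipeline writes a
  manifest of output checksums.
- Problem sizes in the acceptance script — 200 transcripts for projection,
  500 for phase contiguity, 1,000 sequences for digestion, 100 set-cover
  instances, 200 switch replicates — are the package's chosen desk-scale
  study conditions; each quantity is recomputed from scratch at run time.
- Degenerate inputs: N bases translate to `X` rather than failing; empty
  variant sets project to the reference identity; regions without hets
  count as fully phased; a zero-pair switch comparison reports rate 0.

## Known limitations

- Only biallelic variants are supported; multi-allelic sites are removed
  rather than decomposed.
- Variants spanning CDS/intron boundaries are skipped, not projected.
- Splice-category calling for novel isoforms is reduced to a binary
  reference/novel flag; structural subcategories are out of scope.
- Quantification, FDR estimation (q-values are consumed, not computed) and
  spectrum-level rescoring are out of scope.
- The decoy scheme is whole-sequence reversal with collision shuffling;
  per-peptide pseudo-reversal variants are not implemented, and the choice
  is isolated behind `generate_decoys`.
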