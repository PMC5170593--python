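# Methods

This note records the models, conventions and design decisions behind the
package, in the spirit of a methods supplement: what each stage assumes, the
parameters that matter, what the synthetic data does and does not emulate,
and where the design was genuinely open.

## Scope and hand-off points

The pipeline consumes what an external aligner + caller would produce:
per-accession allele-depth observations (chrom, pos, ref, alt, D_R, D_A).
Alignment itself (BWA) and pileup genotyping (samtools/bcftools) are out of
scope; their quality gates (base/mapping quality) are treated as already
applied upstream. The candidate rule that `bcftools view -p 0.9` enforces —
report a locus when more than 10% of reads differ from the reference — is
re-implemented directly on the depth table, so the cascade is fully auditable
and testable without alignments.

## Read QC

Thresholds (all strict comparisons, exactly as the rules are stated):
`max_n_fraction = 0.05`, `min_mean_quality = 20` (Phred), `trim_quality_floor
= 13`, `min_length_after_trim = 40` bases. Decisions that the rule statements
leave open, and how they were resolved:

- **Rule order** is N → mean quality → trim → length → dedup; a pair removed
  by an earlier rule is attributed only to that rule. Order affects report
  bookkeeping, not the retained set.
- **Mean quality is computed on the untrimmed read**, since trimming is
  listed after the mean-quality rule.
- **The duplicate key is the trimmed sequence of both mates**, qualities
  ignored, orientation as stored. Sequence identity is the minimal faithful
  reading of "duplicates from a single amplicon"; dedup is listed after
  trimming, hence trimmed sequences.
- "Less than 40" is read as bases (no unit is stated).
- A zero-length mate is malformed input, not a removable read.

The file interface reads plain or gzipped FASTQ (Phred+33) and errors on
desynchronized mate ids or truncated records. Gzip output is written with a
zeroed mtime so identical runs are byte-identical.

## Variant filter cascade

`FilterThresholds` defaults: `min_alt_fraction = 0.10`, `min_allele_depth =
3`, `het_low = 0.2`, `het_high = 0.8`, `min_maf = 0.05`.

- **Zygosity interval.** The heterozygosity criterion is implemented as the
  open interval 0.2 < D_R/(D_R+D_A) < 0.8; the boundary ratios are assigned
  homozygous. (The condition as originally printed, 0.2 > r > 0.8, is
  unsatisfiable and is read as a typo for the interval; the open reading
  keeps more data, matching the retention intent of a homozygosity filter.)
  Both bounds are configurable.
- **Genotype semantics at merge.** Per-accession tables contain only sites
  with alternative-read evidence — the shape of a caller's output. At
  population merge: an accession with *no observation* at a site is genotyped
  `ref` (its reads were reference-consistent there); an *observed* site that
  fails candidacy (alt fraction ≤ 10%) is likewise `ref`; a candidate with no
  confident allele, or a heterozygous call in a homozygous line, is
  `missing`. Treating absence as reference is what makes population MAF
  meaningful: if non-called accessions were scored missing, every real
  variant's post-merge minor allele would be the reference allele at
  near-zero frequency and the MAF filter would delete the entire call set.
  This convention assumes every accession has coverage genome-wide — true in
  the simulation, approximately true at ~10× real coverage.
- **MAF denominator.** One vote per accession (a homozygous line's two
  identical alleles are one vote), het counts half toward each allele,
  missing excluded. The filter applies to SNPs; application to InDels is a
  switch, off by default, because the published filter is stated for SNPs
  only.
- **Multi-allelic sites** are not modelled; the simulator never emits them.
  Real input rows carrying two alternative alleles must be split upstream.

## Effect annotation

One representative transcript per gene; categories form a partition, so the
marginal counts always sum to the total (the identity that makes the
published distribution tables internally consistent).

- The **splice window** is the 8 intronic bases on each side of every
  exon–intron junction; splice is a subdivision of introns, so coding
  positions near a junction stay `Syn`/`nonSyn`.
- Coding SNPs are classified by rebuilding the affected codon in transcript
  orientation (reverse complement on the minus strand) and translating with
  the standard genetic code; stop gain/loss counts as `nonSyn` (no separate
  category exists in the scheme).
- Coding InDels are `frameshift` unless |len(alt) − len(ref)| ≡ 0 (mod 3);
  no special-casing of start-codon-spanning InDels.
- **InDels are placed by their leftmost affected base** (first deleted base
  for deletions; anchor base for insertions), with variants expected in
  left-aligned, anchored VCF representation. For real inputs whose InDels
  span feature boundaries this is the tie-break; the simulator never emits
  boundary-spanning InDels (see below).

## Population summaries

- A locus is **polymorphic within a group** iff ≥2 distinct non-missing
  genotypes occur among the group's accessions; missing is ignored rather
  than treated as a state. Functional columns restrict to the
  protein-changing categories.
- **Windowed tracks** use non-overlapping fixed windows anchored at position
  1 (default 500 kb for genome-scale data; the analysis scripts use 10 kb on
  the toy genome). Heterozygosity per window is the fraction of pre-filter
  zygosity calls classified het among all observations in the window — het
  calls exist only pre-filter for homozygous lines, so the track is computed
  from the depth observations, not the filtered matrix. This per-call
  fraction is one defensible estimator; the exact estimator behind the
  published genome tracks is not stated.
- InDel length histograms are signed (insertions positive), overall and
  coding-only; the coding histogram covers exactly the frameshift +
  nonframeshift variants.

## KASP site selection

Flank uniqueness is exact 50-mer matching, counting both strands, with the
flank's own locus as the single permitted occurrence; exactness was chosen
for determinism (a mismatch-tolerant search would need an arbitrary
similarity threshold the criteria do not state). Only SNPs are screened;
InDels participate only as co-sited contaminants. Statuses are mutually
exclusive and record the first failing criterion in the order
near-edge → non-unique flank → co-sited variant.

## Synthetic data generator

What it emulates: a small multi-chromosome genome (default 2 × 50 kb) with
one-transcript gene models (≥2 exons, introns ≥20 bp so adjacent splice
windows never collide, non-empty UTRs, CDS = start codon + non-stop codons +
stop); a population of morphotype groups of homozygous accessions (optional
genebank accessions may be heterozygous); planted SNPs/InDels with known
category and per-group alternative-allele frequency; paired-end reads at a
chosen fold-coverage with base-call errors and planted QC failures; and
per-accession depth tables with injected error-only sites.

Key choices:

- **Category fidelity by construction.** Variant planting is validated
  against the effect annotator itself (rejection sampling), so manifest
  categories and re-annotation agree 100% by design; the annotator is in
  turn checked against an independent full-protein-retranslation oracle in
  the tests, keeping the two validations independent.
- **InDels** are anchored, left-aligned (candidate placements that could
  shift left are rejected), drawn over ±1..10 bp, and confined to a single
  feature interval — including to one side of the splice-window boundary —
  so classification is independent of representation and of strand
  mirroring. The elevated weight of 3n lengths inside CDS is expressed
  through the category mix (nonframeshift > frameshift by default),
  reproducing the coding-region enrichment of multiples of three.
- **Default category mix** weights genic categories up relative to published
  genome-wide proportions because the toy genome is far more gene-dense than
  a real crop genome; every category receives enough mass to be exercised.
  Group allele frequencies default to Uniform(0.05, 0.95) — a flat spectrum
  that exercises both sides of the MAF threshold; the generator accepts
  fixed and Beta spectra as well.
- **Depth model.** Site depth N ~ Poisson(depth) conditioned ≥1; each read
  carries the true allele and flips to the other allele with probability
  `error_rate`, so a hom-ref site shows D_A ~ Binomial(N, e) — conservative
  in that every error is assumed to support the alternative allele. This is
  a stand-in, not a claim about any sequencer's error structure. Error-only
  sites are injected at 2×10⁻⁴ per bp per accession by default so the
  cascade has false candidates to remove.
- **Reads** are sampled from the accession's hom-alt haplotype with distinct
  fragment starts per chromosome (clean pairs can never be accidental
  duplicates of one another), qualities 30–41 for clean calls and 15–25 at
  error positions. Planted failures are mutually exclusive per pair and
  constructed to fail exactly one rule: >5% N with intact qualities; mean
  quality <20 without sub-13 bases; a sub-13 3′ tail long enough to leave
  <40 bases while keeping the untrimmed mean ≥20; exact duplicates of an
  earlier clean pair. Heterozygous genotypes are not phased into reads (the
  read stream is the QC substrate; QC never inspects genotypes). There is no
  fragment-size or adapter modelling, no alignment output, and no
  triplicated-subgenome structure.

What passing tests therefore show: the rules are implemented exactly as
specified and recover planted truth under idealized noise. They do not show
robustness to alignment artefacts, indel-realignment errors, multi-allelic
sites or coverage heterogeneity beyond Poisson.

## Determinism and problem sizes

All randomness flows through seeded numpy generators; identical (config,
seed) reproduce byte-identical data outputs (gzip written with zeroed
mtime). The run report records wall times and is the one file excluded from
the byte-identity contract. The validation suite and the acceptance script
use a 50 kb genome with 500 planted variants, 15 accessions at 10× depth,
1,000 read pairs with each failure kind at 5%, 10,000 random depth
observations and 1,000 oracle-checked coding SNPs — sizes at which every
oracle (quadratic QC reference, exhaustive 50-mer scans, full-protein
retranslation) is itself exact.

## Known limitations

- One transcript per gene; no consequence ranking across transcripts.
- Genotypes carry no likelihoods — the retained information is depth ratios
  only, as in the filtering rules themselves.
- The absence-means-reference merge convention is appropriate for uniformly
  covered data; low-coverage accessions would need explicit missingness
  upstream.
- KASP flank uniqueness is exact-match only; near-matches that would still
  cross-amplify are not detected.
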