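# Methods

This note documents the models, conventions and numerical choices behind
`gbstag`, what the synthetic-data generator does and does not emulate,
and the problem sizes used by the test suite and the acceptance script.

## Read anatomy and classification

A GBS read is `barcode + cut-site remnant + genomic sequence`. A read is
classified GOOD when (a) it starts with exactly one barcode from the
lane's key (exact match — barcodes within a lane are validated to be
unique and prefix-free, which makes matching unambiguous and
order-independent), (b) the barcode is immediately followed by one of
the enzyme's cut-site remnants, (c) no N or other ambiguity code occurs
within the 64-base (configurable `trim_length`) window after the
barcode, and (d) the resulting tag is at least `min_tag_length` bases.
All other reads are classified (NO_BARCODE / CONTAINS_N / TOO_SHORT),
never errored. Base quality scores are ignored throughout; tag
recurrence across the experiment is the quality signal.

Choices made where behavior was genuinely open:

* **Remnant check.** The remnant-immediately-after-barcode requirement
  is enforced by default, with `require_remnant=False` for protocols
  whose barcode already includes the remnant. A read failing the check
  is structurally not a barcoded GBS read, so it is binned NO_BARCODE.
* **Chimera trimming.** The post-barcode window is scanned for a full
  internal recognition site (IUPAC patterns allowed, e.g. GCWGC),
  starting just past the leading remnant. The tag is truncated so it
  ends at the last base *before* the internal site begins: the
  remnant-side bases are kept, the site and everything after it are
  dropped. Trimming runs after the 64-base truncation.
* **`min_tag_length` = 20.** Shorter post-trim tags carry too little
  sequence to place uniquely on a reference; 20 bases is a conservative
  floor for a plant-sized genome.
* **Enzyme catalogue as data.** Supported enzymes (ApeKI, PstI,
  PstI–MspI, EcoT22I) live in `gbstag/data/enzymes.json`
  (remnants + internal patterns) and are user-extensible without code
  changes.

## Tags and the master list

Tags pack A/C/G/T two bits per base (A=00, C=01, G=10, T=11) into a
128-bit payload, first base most significant, high bits zero, with the
length stored explicitly — so a tag is the pair (packed bases, length),
equality and the total ordering are over that pair, and a 64-base tag
occupies exactly 16 bytes. Per-file tag counting is exact; merging is a
k-way merge of sorted tables, and the master list keeps tags with
experiment-wide count ≥ `min_count` (default 5 — deliberately
conservative; the threshold trades admitted sequencing error against the
lowest allele frequency of interest, and is exposed everywhere). The
master list is exported as FASTQ with uniform fake qualities for an
external aligner.

## TOPM: positions and uniqueness

The SAM produced by the aligner is imported with pysam. Every master tag
gets exactly one entry: UNIQUE, MULTIPLE or UNALIGNED, so the three
statuses always partition the master list. "Unique best" is
operationalized as: a mapped primary record, no equal-score alternative
(XS ≥ AS, or an equal-score secondary record), and MAPQ ≥ `mapq_min`;
MAPQ 0 without an AS tag counts as MULTIPLE. Coordinates are 1-based;
`cut_pos` anchors the cut-site end of the tag — the leftmost aligned
base on `+`, the rightmost on `−` — so the two tags flanking one cut
site land at stable strand-specific coordinates two bases apart (for a
5-base recognition site). Variants are recorded per tag as (alignment
column, allele), at most `max_variants` = 8 per tag (a fixed-size record
bound; loci with more retained SNPs keep the earliest columns). The TOPM
persists as TSV, checksummed binary, and an HDF5 container, all
round-trip tested.

## TBT: depths

Depths are single bytes saturating at 127 (kept at 127 rather than 255
to preserve the established depth semantics of the format family).
Replicate taxa merge by capped sums. Persistence is a run-length
encoding with 1-byte run headers (zero runs vs literals; isolated single
zeros fold into literals because a run token would cost more than the
byte it replaces) and a crc32 per row. The encoding is lossless always,
strictly smaller than raw for matrices with ≥ 50% zeros, and ~3–4× for
90% zeros. Note the *synthetic* default dataset is only ~30% zeros —
the generator's populations share a handful of haplotype tags per locus,
whereas real species-wide builds derive their extreme TBT sparsity from
tag diversity across tens of thousands of samples; compression strength
is therefore verified on matrices with representative sparsity rather
than on the simulated default.

## TagLocus alignment

Tags sharing (chrom, strand, cut position) are aligned progressively:
guide order is most-frequent-first (TBT row sums, tie-broken by tag
order), each new sequence is aligned to the running consensus by
Needleman–Wunsch (match +2, mismatch −1, gap −3), and new gaps propagate
into all previous rows. The 5′ ends are anchored (tags share the cut
site) so leading gaps are penalized; trailing gaps are free because tags
legitimately differ in length. Traceback prefers diagonal over up over
left, making alignments deterministic. For two-tag loci this is exactly
one optimal pairwise alignment, and the test suite checks the score
against an independently written DP oracle; for larger loci the contract
is *consistent* indel placement, not equivalence with any particular MSA
program. Alignment column c maps to reference coordinate
`cut_pos + c` (`+` strand) or `cut_pos − c` (`−` strand); minus-strand
alleles are complemented to reference sense when SNP candidates are
assembled.

## Genotype calling

The caller compares three binomial likelihoods on the top two allele
depths (see README). Defaults: per-base error `e` = 0.01,
`lr_threshold` = 1 (pure maximum likelihood). The likelihood-ratio
threshold demands that the best homozygote beat the heterozygote by that
factor; ties and sub-threshold ratios call the heterozygote, the
conservative choice at low coverage. This three-hypothesis construction
is this package's own reconstruction of quantitative binomial-ratio
calling; every constant is configurable. Taxa whose depth at a site
comes only from third-or-lower alleles are left missing; sites with more
than two alleles are kept with genotypes over the two deepest alleles
(frequency ties broken lexicographically).

Heterozygote calls are still made for pedigree-designated inbred taxa:
the pedigree feeds the filters, never the caller.

## Filters

Retention requires (standard defaults in parentheses): locus
coverage ≥ `min_locus_coverage` (0.1), q ≥ `min_maf` (0.001),
F_IT ≥ `min_fit` (0.8), and — when a pedigree is supplied — inbred
coverage > `min_inbred_coverage` (0.15) and inbred het
score < `max_inbred_het_score` (0.21). The strict/non-strict comparison
senses follow the standard build's stated operators. Monomorphic sites
(He = 0, F_IT undefined) always fail. Without a pedigree the
inbred-specific clauses are skipped and q/Ho/F_IT are computed over all
taxa; with one, over the inbred subset (F ≥ `min_f`, default 0.8) — the
same subset feeds all inbred-based statistics, including the coverage
denominator.

## Production

Reads are trimmed by the identical rules, then matched exactly
(sequence + length) against variant-annotated TOPM tags via an index on
the leading 32-base prefix with full verification, longest candidate tag
first. Matched tags add their variant alleles to their sample's depth
tally; replicate lanes of one sample sum before calling; per-site allele
depths cap at 127. Strand-mates discovering the same reference position
merge into one site in reference sense. Reads matching tags with no
recorded variants are counted in the report only. The VCF REF allele is
the reference base when a reference is supplied (noted in the header),
else the major allele; gap alleles become indels anchored at the
preceding base. HapMap heterozygotes use IUPAC codes (indel sites use
+/−/0), missing is N.

## RIL-family error estimation

Family MAF uses allele counts with heterozygotes counting half toward
each allele (residual heterozygosity exists in F2-derived RILs; the
minor-allele *call* count, used as the error numerator, counts each
het call once). The 1:1 test is an exact two-sided binomial p-value by
tail doubling, capped at 1, on the nearest-integer minor count.
Monomorphic families are deviating by rule (their p-value is below any
practical alpha at n ≥ 19 anyway) and contribute their calls to the
denominator. Summaries report both the per-SNP mean/median and the
pooled rate (total errors / total denominator calls).

## Synthetic data generator

The generator emulates: a reference with recognition sites planted at a
configurable expected spacing *and scrubbed everywhere else* (so the
cut-site truth list is exact); inbred taxa (homozygous up to residual
heterozygosity 0.5^`selfing_generations`), outbred taxa in Hardy–
Weinberg proportions, biparental F2-derived RIL families segregating
parental alleles ~1:1, and blank negative controls; reads of the
canonical anatomy with per-taxon per-locus depth ~ Poisson(`mean_depth`)
and substitution errors at `error_rate` per base (never in the
barcode/remnant unless `errors_in_barcode` is set — a documented switch);
and full provenance (every read's taxon, locus, haplotype and error
count). True SNPs are placed inside tag footprints, away from site
cores, and alt alleles are rejected if they would create a recognition
site nearby.

A truth-based SAM writer stands in for the external aligner: each master
tag is placed at the locus whose reads generated it (sequence-level
provenance), tags generated by more than one locus become MAPQ-0
ambiguous placements, unknown sequences unmapped. Re-assigning one locus
of a pair to the other's coordinates simulates paralog-merged loci — the
excess-heterozygosity failure mode the F_IT filter targets.

Defaults mirror the assay's intended regime: 1 Mb reference, ~1 cut site
per kb (a realistic density for a 5-base cutter after scrubbing), 96
taxa with 80% inbred, 500 true SNPs with allele frequencies uniform on
[0.1, 0.5], mean depth 2 (the low-coverage 0.5–3× regime), error rate 0
unless the experiment injects it.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: indel sequencing errors (indels
occur only as true variants), PCR duplicates and fragment-size
selection, paired ends, base-quality structure (irrelevant here: the
pipeline ignores qualities), reference mis-assembly, and maize-scale tag
diversity (see the TBT sparsity note above). Site spacing must exceed
the 64-base tag footprint (the planter enforces a minimum gap), so
overlapping loci from adjacent sites are rare in simulation though legal
in the pipeline.

## Problem sizes and determinism

Everything is a pure function of (config, seed); NumPy `default_rng`
streams are derived from the config seed, and hypothesis-based property
tests are derandomized. The test suite and acceptance script run
deliberately desk-scale experiments (the properties they check are
scale-free):

* clean end-to-end run: 200 kb reference, ~250 cut sites (~500 loci),
  48 fully inbred taxa, 100 true SNPs, depth 10, no error
  (~70 k reads);
* filter-efficacy runs: same scale, 90% inbred, 120 SNPs, depth 6, 6
  paralog-merged locus pairs, at 1% and 0.1% per-base error
  (~140 k reads each);
* estimator run: 8 RIL families × 30 lines, 200 SNPs, injected call
  error ∈ {0, 0.005, 0.02}.

The clean run uses a fully inbred population because exact (100%)
genotype recovery is only well-defined when heterozygotes cannot be
under-sampled: a true heterozygote seen on only one allele is
*correctly* called homozygous by maximum likelihood, so mixed
populations bound concordance below 1 at any finite depth. Truth
recovery is asserted against the *discoverable* SNP set: true SNPs both
of whose alleles survive the master-list count threshold and which
segregate among the sampled genotypes; variants below those floors are
invisible to any tag-counting method by construction.

## Known limitations

* Tag length is capped at 64 bases and depths at 127, by design of the
  storage formats.
* The progressive MSA is not guaranteed optimal for loci of ≥ 3 tags.
* `UNALIGNED`/`MULTIPLE` tags are carried but never rescued (no genetic-
  map placement).
* No imputation, phasing, LD-based filtering, or alternative genotype
  callers.
* The binomial caller assumes symmetric, site-independent errors; real
  error rates grow along the read, which only the RIL-family error
  estimator can expose after the fact.
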