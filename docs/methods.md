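# Methods

`triokin` implements two connected analyses for small family-exome studies
of a rare disease (here: cryptogenic cholestatic liver disease in young
adults): (i) trio/duo segregation filtering of annotated exome variants with
a rarity/deleteriousness cascade and a gene-panel candidate scan, and
(ii) a resampling statistic that detects undisclosed parental consanguinity
from excess sharing of rare variants.  Because family exome data of this
kind cannot be redistributed, the package carries a synthetic generator
that reproduces the statistical structure of such a study (pedigrees,
Hardy–Weinberg founders, Mendelian transmission, annotation labels), so
every stage is testable at desk scale.

## Variant model and ingest

Variants are bi-allelic records keyed by `(chrom, pos, ref, alt)` with
1-based VCF coordinates.  Multi-allelic VCF lines are split on ingest: the
record for alternate allele *k* maps input allele index *k* to 1 and every
other non-reference index to reference-equivalent 0, preserving each
sample's total count of non-reference alleles across the output records.
No indel left-alignment or normalisation is attempted; the matching key is
the literal post-split tuple.

Annotations (gene symbol, consequence, impact, SIFT/PolyPhen labels,
population allele frequencies) are consumed, never computed: either from a
VEP-style `CSQ` INFO field whose `|`-separated layout is declared in a
small config, or from a tab-delimited sidecar keyed by variant.  When a
variant carries several transcript annotations, the block with the most
severe impact is kept (tie → first listed).  Missing fields stay missing —
in particular a missing allele frequency is *not* zero; it marks a variant
absent from the reference panel.

Sites absent from a sample's VCF are genotype-missing rather than assumed
homozygous-reference: per-sample call sets rarely emit reference lines, and
imputing hom-ref would manufacture recessive genotypes.  The cost is a
conservative bias — union sites can only disqualify, never create, a
segregation call.

## Segregation filters

All classifiers share three conventions: a variant homozygous-alternate in
an *unaffected* parent is never reported; a missing genotype disqualifies a
variant from any positive call (no imputation); hemizygous-alternate male-X
genotypes count as homozygous-equivalent.

* **Recessive homozygous** — trio: child hom-alt and both parents het;
  duo (one parent available): child hom-alt and that parent a carrier but
  not hom-alt.  On male-X sites a haploid father can never satisfy "het",
  so the trio rule cannot fire there; the mother-duo rule is the operative
  X path.  This follows directly from treating hemizygous-alt as
  homozygous-equivalent and is deliberate: X-linked models beyond
  hemizygote bookkeeping are out of scope.
* **Dominant** — two modes behind a switch, because small studies use
  either: `de_novo` (child het, all available parents hom-ref) and
  `affected_parent` (child het, and the carriers among the parents are
  exactly the affected ones).
* **Compound heterozygous** — within one gene, two child-het variants, one
  carried by exactly one parent and the other by exactly the other parent,
  i.e. in trans by parental origin.  Requires both parents; duo input
  raises a phase-undetermined error instead of silently returning nothing.

The **cascade** counts, per child, the fixed ladder recessive → rare →
nonsynonymous → deleterious-in-silico, each stage filtering the previous
stage's survivors, so the counts are monotone non-increasing by
construction.  *Rare* means the selected population's MAF is missing
(novel) or strictly below the threshold (default 0.01, global population).
*Nonsynonymous* means protein-altering (missense, stop gain/loss, start
loss, frameshift, in-frame indel) or splice-affecting; splice donor/
acceptor always qualify, `splice_region_variant` only at impact ≥ MODERATE
so LOW-impact near-splice synonymous calls do not flood the reports.
*Deleterious in silico* means SIFT deleterious (either confidence), or
PolyPhen probably/possibly damaging, or annotator impact HIGH; missing
predictors never rescue a variant.  `possibly_damaging` counts as damaging
because clinical candidate reporting treats it as a positive signal; the
whole ladder is a screen, not a classifier.

## Panel scan

Gene panels are plain symbol lists (uppercased, deduplicated) in five
categories: cholestatic-disease genes, bile-acid metabolism, bile
secretion/transport, other liver-disease genes, lipid metabolism.  A
child-carried variant is reported under every category containing its gene
provided it is nonsynonymous, not hom-alt in an unaffected parent, and
rare — or explicitly whitelisted as a reportable common polymorphism (the
pattern of a well-known functional polymorphism that a clinical report
lists alongside rare findings; whitelist entries are `chrom:pos:ref:alt`
or `GENE:p.change`).  Matching is by gene symbol, not coordinates, because
panels exported from pathway/disease databases are symbol lists.  The
built-in lists are small illustrative panels around the canonical
hereditary-cholestasis genes (ATP8B1, ABCB11, ABCB4, …); real analyses
should supply their own exports.

## Consanguinity statistic

For a parent pair, repeat `n_reps = 100` times: from each chromosome
(1–22 and X; Y excluded) pick uniformly at random one variant that the
father carries and whose population MAF `p` satisfies `0 < p < t` for the
MAF cutoff `t ∈ {0.01, 0.02, 0.05, 0.1}`; count how many sampled variants
the mother also carries (`observed`), and accumulate the Hardy–Weinberg
probability that an unrelated individual carries each sampled variant,
`1 − (1 − p)²` (`expected`).  Frequencies come from the European panel by
default, since the expectation must match the population the parents are
drawn from.

Design decisions, with reasons:

* **Ratio orientation** is observed/expected: high values indicate
  relatedness.  Under kinship φ the probability that the mother carries a
  rare variant the father carries is ≈ 2φ + 2p, so the pooled ratio
  concentrates near `1 + φ/p̄` — second cousins (φ = 1/64) give a few-fold
  excess and the signal grows both with kinship and with rarity, which is
  why the tightest cutoff is the most informative.
* **Family-level scalar** is the pooled ratio Σobserved/Σexpected over all
  repetitions, not the mean of per-repetition ratios: with very rare
  variants per-repetition observed counts are frequently 0 and individual
  ratios are unstable or undefined, while the pooled estimator is defined
  whenever any expectation accrued.  Per-repetition ratios are still
  emitted for distribution plots.  Conditional on the sampled variants the
  expected total equals the mean of the observed total for unrelated
  parents, so the pooled ratio is calibrated at 1 without any tuning.
* **Eligibility** requires a present, non-zero MAF: a variant with missing
  or zero panel frequency has HWE expectation 0 and would degenerate the
  ratio.  "Present in" means carrier (≥ 1 alternate allele) for both
  father eligibility and mother sharing; identical-allele matching
  (`chrom,pos,ref,alt`) is required.  Chromosomes with no eligible variant
  are skipped in that repetition, so a repetition may sample fewer than 23
  variants.
* **Baseline**: fathers from different families are paired against each
  other (one plays "father", the other "mother") to produce an empirical
  unrelated-population distribution of the same statistic.  This is only
  meaningful over a shared (jointly called) site panel; pairing call sets
  with disjoint sites cannot observe sharing.
* The RNG is an injectable seeded `numpy` generator; identical seeds give
  bit-identical results.

## Synthetic data generator

The generator emulates the inputs such a study consumes; its defaults are
the package's study conditions and are fixed.

* **Site-frequency spectrum** — 5,000 unlinked sites allocated across
  chr1–22 and X proportionally to protein-coding gene content; 95% of
  sites draw their global MAF log-uniformly from the rare band
  (0.004, 0.01), the rest from a Beta(2, 5) rescaled onto (0.01, 0.5);
  2.5% of sites are indels.  The European frequency is the global draw
  times a bounded multiplicative noise factor in [0.8, 1.2], so
  population-selection code paths see genuinely discordant panels.  The
  rare band is deliberately concentrated near the 1% cutoff: a
  desk-scale panel of 5,000 sites gives a father only ~2·E[p]·n rare
  carried variants, and frequencies below ~2×10⁻³ contribute almost no
  eligible sites at this size — simulating them would add dead weight
  without information.  This was fixed by a design-stage power analysis of
  the statistic before the validation suite was written; at these
  settings the kinship-sensitivity study has stable power while unrelated
  calibration stays exact (it is threshold-free by construction).
* **Pedigrees and gene dropping** — founder haplotypes are independent
  Bernoulli(MAF) draws (HWE); each transmission passes one uniformly
  chosen allele per parent; X transmission respects sex (fathers pass
  their single X to daughters only; sons are hemizygous for a maternal
  allele).  Builders produce the validation relationships: unrelated
  (φ = 0), second cousins (1/64, parents sharing a great-grandparent
  couple), first cousins (1/16), siblings (1/4); the kinship coefficient
  of every built pedigree is verified against the standard recursion.
* **Annotation labels** — gene symbols are assigned by tiling consecutive
  sites into non-overlapping intervals (the clinically relevant panel
  genes placed on their real chromosomes, every tenth block left
  intergenic); consequence/impact and SIFT/PolyPhen labels are drawn from
  a configurable categorical model (defaults: 42% missense, 40%
  synonymous, 4% HIGH-impact, the rest non-coding/splice-region).
* **Ground-truth injection** — overwrites selected sites to realise each
  filter class exactly (nested recessive ladder, compound-het pairs in
  trans, de novo, per-category panel hits) and emits a manifest.  For
  exact-recovery fixtures the background is neutralised: spontaneous
  recessive-homozygote patterns become het/het/het trios, potential
  compound-het partners are made biparental, and rare nonsynonymous
  background variants inside panel genes are relabelled synonymous — all
  rewrites Mendelian-consistent, none touching injected sites.
* Everything is deterministic under a fixed seed.

What the generator does **not** model, and hence what passing tests do not
show about real data: linkage disequilibrium (irrelevant to the
one-variant-per-chromosome statistic, but real compound-het and ROH
structure is LD-shaped); sequencing error, coverage variation and missed
calls; an ultra-rare tail below 2×10⁻³ at the default panel size;
population stratification between the annotation panel and the family
(EUR frequencies are treated as the true founder frequencies);
annotation error.  The injected-fixture tests show the plumbing is exact,
not that the filters have clinical sensitivity on real exomes.

## Problem sizes and numerical choices

The validation suite uses 50 unrelated pairs for calibration and
3 batches × 20 pairs per kinship level for sensitivity, 5,000 sites per
pair and 100 repetitions per threshold — sizes chosen so the whole suite
runs comfortably on one CPU while keeping the batch-mean standard errors
a few percent of the effect sizes.  Rank concordance is assessed on batch
means (a single pair's pooled ratio is integer-quantised by its handful
of shared variants, so pairwise φ = 0 vs 1/64 ordering is noise-dominated
by design of the statistic, not by implementation).  The φ = 0 baseline
quantile for the separation check is estimated from the 60 pooled
unrelated pairs.  Ties in transcript severity break toward the first
listed block; karyotype order (1–22, X, Y, MT) sorts every output;
undefined ratios (zero accrued expectation) are reported as null/NA, never
as 0, except where a summary explicitly treats "no sharing observed" as a
zero ratio.

## Known limitations

Duo families cannot support compound-het phasing (explicit error) or the
consanguinity statistic (skipped with a note).  The recessive trio rule
does not fire on male-X sites (above).  Gene-symbol matching inherits any
symbol drift between annotation releases and panel exports.  The
common-polymorphism whitelist is a reporting convenience, not an
association claim.
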