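# Methods

This note documents the statistical model behind `cscakut`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Setting

The package targets the common design of rare-disease genetics: a small
case series (tens of individuals with a composite phenotype, here
co-occurring congenital scoliosis and congenital anomalies of the kidney
and urinary tract) contrasted against a large in-house control panel
(thousands of samples). At this scale single-variant tests are hopeless;
inference proceeds by collapsing ultra-rare variation within genes
(burden tests), within gene sets (pathway enrichment), and at the level of
copy-number variants overlapping genes.

## Variant selection and mask weights

Qualifying variants must satisfy, inclusively:

* gnomAD population-max allele frequency &le; 0.1% (missing = 0),
* cohort allele frequency &le; 0.1% (missing genotypes excluded from the
  denominator),
* minor allele count (MAC) &le; 5 and mask weight &gt; 0 for burden
  eligibility.

Each variant is assigned one of six severity **mask levels** by a
first-match-wins rule list over its annotation (consequence class, LoF
confidence, count of damaging in-silico predictors). The default scheme —
level 1 high-confidence LoF (weight 1.0), 2 low-confidence LoF (0.9),
3 in-frame indel (0.7), 4 missense with &ge; 3 damaging predictor calls
(0.5, flag "m"), 5 other missense (0.3, "m"), 6 synonymous/other (0.0) —
spans weights 1 &rarr; 0 across the six levels. The concrete cutoffs are
declared configuration (overridable from a TSV), not a claim about any
particular study's unpublished scheme. Multiallelic sites are split per
alt allele; per-gene assignment uses the single (canonical-transcript)
annotation row per variant.

## Gene burden statistic

The burden of gene *g* in individual *i* is

&nbsp;&nbsp;&nbsp;&nbsp;B(i, g) = max { w(v) : v eligible in g, dosage(i, v) &ge; 1 },

zero for non-carriers; heterozygous and homozygous carriage count alike.

Association is tested with logistic-regression **score** components

&nbsp;&nbsp;&nbsp;&nbsp;T = U&sup2;/V, U = &Sigma; x&#7522;(y&#7522; &minus; y&#772;),
V = y&#772;(1 &minus; y&#772;) &Sigma; (x&#7522; &minus; x&#772;)&sup2;,

one per mask level present in the gene (on the level-restricted burden)
plus, for genes with two or more levels, one on the overall max-weight
burden. Component evidence is pooled with the Cauchy (ACAT) combination

&nbsp;&nbsp;&nbsp;&nbsp;T&#8320; = &Sigma; w&#7522; tan((0.5 &minus; p&#7522;)&pi;) / &Sigma; w&#7522;,&nbsp;&nbsp;
p = 0.5 &minus; arctan(T&#8320;)/&pi;,

with the mask weights as combination weights (the overall component takes
the largest level weight). The combination is numerically stabilised for
p &lt; 10&#8315;&sup1;&#8310; (tan &rarr; 1/(&pi;p)) and for very large T&#8320;.

### Calibration of sparse genes

Nearly every gene in an ultra-rare scan has only a handful of carriers.
There the asymptotic &chi;&sup2;&#8321; reference for T is anti-conservative, the
exact permutation tail is heavily discrete (hence conservative), and the
Cauchy combination inherits the dependence between its components. The
package therefore treats genes with fewer than 10 carriers — essentially
all of them under the null — exactly: the Cauchy-combined statistic is
recomputed for **every** assignment of case labels to the gene's carriers
(2^k configurations, each weighted by its hypergeometric probability),
and the reported p-value is the fuzzy (randomized) permutation tail

&nbsp;&nbsp;&nbsp;&nbsp;p = P(T&#8320; &gt; t&#8364;&#8346;) + U &middot; P(T&#8320; = t&#8364;&#8346;), U ~ Uniform(0,1),

which is *exactly* Uniform(0,1) under the permutation null regardless of
component dependence. The conservative tail P(T &ge; t) and the mid-p
variant are available via `mode=`; the fuzzy default is what keeps the
genome-wide QQ plot on the diagonal and the type-I rate at its nominal
level — with the single caveat, inherent to fuzzy p-values, that repeated
analyses of the same data differ within the tie band unless the seed is
fixed (the scan seeds all draws from one generator). Genes with &ge; 10
carriers use the asymptotic score reference per component and combine
p-values directly; such genes are vanishingly rare under ultra-rare
filtering, and for 10–30 carriers the asymptotic and permutation answers
agree within Monte-Carlo error (property-tested).

Alongside the burden p, every gene receives a two-sided Fisher's exact
test on carrier counts (computed by exact integer enumeration of the
hypergeometric support, so ties are resolved without floating-point
slack), an odds ratio with the Haldane–Anscombe 0.5-cell correction
whenever a cell is zero, and a Woolf log-OR &plusmn; 1.96 SE confidence
interval. The choice of zero-cell correction is declared, not claimed to
match any particular publication. No multiple-testing correction is
applied to the primary p-values; Bonferroni and Benjamini–Hochberg columns
are emitted as extras. QQ diagnostics report genomic inflation
&lambda; = median(&chi;&sup2;&#8321;-quantile of p) / median(&chi;&sup2;&#8321;).

## Pathway enrichment

For a gene set S, each individual's total score is &Sigma;_{g&isin;S} B(i,g),
which enters logit P(case) = &beta;&#8320; + &beta;&#8321;&middot;score. The
reported odds ratio exp(&beta;&#8321;) is per unit of total score. Standard
IRLS fits report Wald CIs and p-values; detected separation or
non-convergence (common with 40-case-scale data and rare scores) falls
back to Firth's bias-reduced fit with a penalized likelihood-ratio p and a
`separation_flag`. No covariates and no set-size adjustment are applied;
source databases are carried as labels only.

## CNV association

CNV calls and gene models share a 0-based half-open interval convention.
Each CNV is classified against gene boundaries: `intragenic` (fully inside
one gene; coterminous counts), `multigenic` (&ge; 2 genes), `intergenic`
(none), plus `partial` for the single-gene-overlap-but-extending case the
trichotomy does not cover (partial overlaps still count toward the gene's
score). The gene-level score is the sample-deduplicated carrier count per
(gene, loss/gain) — the simplest reading consistent with a 2&times;2
case/control test; `count_events` and `bp_overlap` aggregation modes are
available for descriptive use. Losses and gains are tested separately.

Association uses the Pearson &chi;&sup2; (1 df, no Yates correction by
default). Because carrier tables are sparse, whenever any expected cell is
below 5 the reported p-value is the *complete* label-permutation tail of
the Pearson statistic — enumerated through the hypergeometric distribution
of the case carrier count, i.e. exhaustive label shuffling without Monte-
Carlo error. On such tables the asymptotic &chi;&sup2; p would be wildly
anti-conservative (a 2-carrier gene with both carriers in cases reaches
p &asymp; 10&#8315;&sup1;&#8304; asymptotically versus an exact 2&times;10&#8315;&sup3;).

## Synthetic cohort generator

The generator produces every input the pipeline reads, with the structure
the analysis assumes, and is a pure function of (config, seed).

* **Genome**: `n_genes` genes (default 2,000) tiled every 10 kb (5 kb
  long) over two toy contigs. Coordinates are internally consistent; no
  sequence content.
* **Carriers, not site frequency spectra**: per gene, a control qualifying-
  carrier rate q is drawn uniformly from 5&times;10&#8315;&#8308;–2&times;10&#8315;&sup3;
  per gene (order-of-magnitude realistic for ultra-rare qualifying
  variation; configurable, scalar allowed). Cases carry with probability
  OR&middot;q / (1 &minus; q + OR&middot;q), OR = 1 except for configured
  risk genes (defaults: four genes with carrier ORs 20–80). Each carrier
  receives 1–2 private heterozygous variants. Because the configured rate
  is defined as the probability of carrying a *qualifying* variant, the
  first variant of every carrier draws from the weight-bearing mask levels;
  second variants draw from the full mask distribution (default masses
  0.05/0.10/0.05/0.25/0.35/0.20 over levels 1–6), which also exercises the
  weight-0 path. Annotation fields are generated to reproduce the intended
  mask under the default scheme; popmax AF is missing for 20% of variants
  and otherwise uniform below 0.1%. Optional common "decoy" variants
  (popmax 5%) verify the filter.
* **Gene sets**: `n_sets` sets of `genes_per_set` genes drawn uniformly
  (overlap permitted); one designated set contains all risk genes.
* **CNVs**: per sample Poisson(`cnv_rate`, default 2) background events
  mixing intragenic/multigenic/intergenic placements (60% losses), plus a
  recurrent-loss mechanism: for each configured CNV risk gene, cases
  acquire a gene-spanning loss with probability `cnv_baseline_loss_rate`
  &times; multiplier (defaults 4&times;10&#8315;&sup3; and 30), controls at the
  baseline rate — so multiplier 1 is an exact null.

What the generator does **not** emulate: linkage disequilibrium, realistic
site frequency spectra, population structure or relatedness, sequencing
artefacts, genotype uncertainty, covariates (sex, ancestry PCs), diploid
phasing. Passing the validation suite therefore demonstrates the
correctness and calibration of the statistical machinery under the stated
sampling model, not robustness to confounding — the upstream QC that
removes such confounding (VQSR, PCA, IBD filtering) is outside this
package's scope and is assumed done.

## Validation design and problem sizes

The validation suite and `scripts/acceptance.py` use these operating
points, chosen as the package's own simulation design:

* **Null calibration**: three cohorts of 2,000 genes at 100 cases /
  2,000 controls; checks the empirical rejection rate at &alpha; = 0.05
  against its binomial 95% CI, QQ &lambda; &isin; [0.9, 1.1], and a KS
  test of p-value uniformity. (The 100/2,000 size keeps per-replicate
  runtime at a couple of seconds while preserving the extreme
  case/control imbalance of the motivating design.)
* **Ranking recovery**: a single spiked gene (carrier OR 50) and one CNV
  risk gene (loss multiplier 30) at a fixed qualifying-carrier rate of
  2&times;10&#8315;&sup3; (the top of the default range — the natural
  operating point for a power study), 100 replicates; and the enriched
  gene set under the default four-risk-gene configuration, 100 replicates.
* **Logistic recovery**: true OR 2 at n = 2,000 (200 replicates, median
  estimate) and null CI coverage at n = 1,000 (500 replicates).
* **Oracle checks**: Fisher vs exact-fraction enumeration over all 2&times;2
  tables with N &le; 60; Cauchy combination vs extended-precision direct
  evaluation on 10&#8308; random inputs; CNV classification vs brute-force
  all-pairs overlap on 10&sup3; CNVs &times; 10&sup3; genes.

## Numerical and degenerate-input conventions

* p-values are clamped to [10&#8315;&sup3;&#8304;&#8304;, 1]; Cauchy inputs at 0/1 are
  clamped into the open interval with a warning.
* Constant burden or score columns are flagged untestable, never assigned
  a p-value; zero-margin 2&times;2 tables likewise.
* Permutation ties are grouped at relative 10&#8315;&#8313; on the statistic.
* All scan-level randomness (fuzzy tails) flows from a single seeded
  generator; genes are processed in sorted order so results are
  reproducible bit-for-bit.
* Result TSVs print p-values with 13 significant digits so a read-back
  reproduces them to 12.

## Known limitations

* The fuzzy p-value is a randomized test; two analysts with different
  seeds obtain p-values differing within the discrete tie band. Fix the
  seed (default 0) for exact reproducibility, or use `mode="conservative"`
  for a classical (conservative) permutation p.
* Firth confidence intervals are Wald-type on the penalized information;
  profile-likelihood intervals would be preferable near separation but are
  not implemented.
* No covariate adjustment anywhere; the package assumes a homogeneous,
  QC'ed cohort.
* The CNV stage tests carrier counts only; the alternative aggregation
  modes are descriptive.
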