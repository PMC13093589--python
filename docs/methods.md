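# Methods

This note records the statistical models behind `recipcross`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical decisions a maintainer would want spelled
out.

## Crossing design

A complete design has M independent 2×2 matrices. Each matrix mates one
hatchery-origin (H) and one natural-origin (N) female to one H and one N
male, producing the four cross types HH, HN, NH, NN (mother first). One
female and one male offspring are sampled per full-sib family, so the
design has 8·M offspring, balanced by sex and cross type. Matrices are
assigned to spawning dates in near-equal leading-heavy blocks (4/4/4/3
over four dates when M = 15); cross date is constant within a matrix and
enters the DE model as a batch covariate.

## Count model and differential expression

Counts are modeled per gene as negative binomial with log link,
`Var = mu + alpha*mu^2`, and design `~ cross_date + sex + group`
(treatment coding, first sorted level as reference; the 2-level contrast
coded last). The estimation chain is deliberately simple so every stage
has an independent oracle and the randomization procedures can call it
thousands of times:

- **Size factors** — median-of-ratios: over genes with nonzero counts in
  every sample, each sample's factor is the median of count /
  gene-geometric-mean, rescaled to geometric mean 1. The median is taken
  on the linear ratio scale (median of log-ratios differs whenever the
  reference gene count is even, because the middle two values are then
  averaged on the wrong scale).
- **Dispersion** — per-gene method of moments on normalized counts
  within covariate cells (samples sharing one combination of the design
  factors), pooled across cells with weights (n_c − 1), floored at
  1e−8. A Poisson or constant gene lands on the floor. No shrinkage
  toward a trend is applied: the estimator must remain a local,
  transparent moment estimate so recovery tests are interpretable.
- **GLM fit** — IRLS with fixed per-gene dispersion, batched across
  genes (one shared design matrix; the per-gene normal equations are
  solved with stacked linear algebra). Convergence: relative deviance
  change < 1e−8, at most 50 iterations; non-converged genes are flagged,
  given missing p-values, excluded from FDR with a logged count.
  All-zero genes are never fit.
- **Inference** — Wald z on the contrast coefficient, reported as log2
  fold change; p from the standard normal; Benjamini–Hochberg step-up
  across converged genes. **Finite-sample SE correction:** reported SEs
  carry a factor sqrt(n/(n − p)). Information-matrix SEs ignore the p
  estimated mean parameters; on no-effect simulations the null Wald z
  standard deviation is ≈ sqrt(n/(n − p)) (measured 1.036 at n = 60,
  p = 6), and the correction restores the raw type-I fraction at 0.05
  to ≈ 0.05. The Poisson-limit oracle test compares the *uncorrected*
  SEs against an external GLM fit.

Sign convention: `run_de(counts, meta, "HH", "NN", ...)` reports
positive log2 fold change for genes higher in HH. Published tables that
take HH as the reference are the mirror image.

### Sibling correlation

Families contribute two siblings each, so the DE model's independence
assumption is mildly violated. Rather than fitting a random-effects
model, the package quantifies the violation: per gene, log2(normalized
count + 1) values are residualized on cross date, sex, and cross type,
and the correlation between the two siblings of a family is estimated as
the one-way intraclass correlation across families. The consensus is the
inverse Fisher-z of the trimmed mean (10 % per tail) of per-gene z
values. On default simulated data the consensus is ≈ 0.13 — small enough
that ignoring family structure costs little, which is exactly the
argument the estimator exists to support. Per-gene ICCs are clipped to
±0.9999 before the z-transform so degenerate (duplicated-sibling) genes
stay finite.

## Randomization procedures

Both procedures canonically sort samples by id before drawing, so a
seed gives identical partitions regardless of input row order.

- **Ancestry gradient.** For constraint N, group A receives exactly N
  HH offspring and no NN, group B exactly N NN and no HH, and the
  remaining slots are filled with reciprocal-cross (HN/NH) offspring
  sampled *without replacement* across both groups. (One description of
  this procedure says the filler is drawn with replacement; the without-
  replacement reading is the default and a `with_replacement` flag
  provides the variant.) DE inside reshuffles keeps the cross_date and
  sex covariates (a flag drops them). At the maximum constraint the
  partition is the empirical HH-vs-NN split; the replicate distribution
  is degenerate there, so it is computed once — the N = max mean always
  equals the direct DEG count exactly and has zero CI width. CIs are
  percentile (2.5, 97.5) across replicates.
- **Conservative permutation.** Only HH and NN offspring are pooled and
  reshuffled into two equal groups. The reported empirical p-value uses
  the add-one convention (1 + #{replicate ≥ observed})/(R + 1), which
  can never be zero and is valid (never liberal) under exchangeability;
  the plain b/R variant is also reported. Because the DEG-count
  statistic is integer-valued and concentrates near zero under the
  null, the conservative p is heavily tied there and cannot be
  uniformly distributed; for calibration diagnostics the result also
  carries the standard *randomized* (tie-smoothed) p-value,
  (#{> obs} + U·(1 + #{= obs}))/(R + 1) with U ~ Uniform(0,1), which is
  exactly uniform under the null and is what the calibration tests
  check with a KS test.

## Inheritance-mode decomposition

For each DEG, standardized log means (log2(normalized count + 1),
mean ± SE per cross group) feed a three-model comparison. Given observed
(HH, NN), the models predict the reciprocal-cross pair (HN, NH):
additive → (mid, mid) with mid = (HH + NN)/2; maternal → (HH, NN);
paternal → (NN, HH). The score is the SE-weighted squared deviation of
the observed pair from the prediction (a 2-df chi-square-scale
quantity). The call is the best-scoring model, declared *ambiguous*
when the runner-up is within 10 % of the best **or** within 6.0 score
units absolutely. The absolute margin matters: on null genes HH ≈ NN,
all three predictions nearly coincide, all scores are O(1), and a
purely relative rule would assign essentially random calls; with the
margin, low-signal genes default to ambiguous and the false-maternal
rate on null genes stays below 10 %. With group SEs ≈ 0.1–0.15 and
effects of 2 log2 units, model score differences are O((effect/2/SE)^2)
≈ 50–70, so genuinely patterned genes are never swallowed by the
margin.

The per-gene `visual_shift` (adding the gene set's grand HH mean minus
the gene's own HH mean to all of that gene's values) is a plotting aid
only; it is an additive per-gene constant and cannot change any
within-gene group contrast.

The direction-bias test for an up/down DEG split reports the standard
1-df goodness-of-fit chi-square against 50:50 plus the exact two-sided
binomial p. For a 290/95 split this statistic is 2·97.5²/192.5 = 98.77;
a published value of 125.35 for that split does not match the standard
1-df computation, whose construction there is unstated — this package
reports the standard formula.

## Genotype procedures

- **Filters**, in fixed order: (1) drop loci missing in > 20 % of
  individuals; (2) drop individuals with > 20 % missing calls over the
  surviving loci; (3) drop invariant loci and loci with minor allele
  frequency < 0.01, frequencies computed after individual removal. The
  report conserves totals by construction and the order is pinned by a
  regression test (a borderline individual is removed under this order
  but not under the swap).
- **Kinship** — KING-robust from identity-state counts,
  φ = (N_het,het − 2·N_oppHom)/(N_het(i) + N_het(j)), restricted to loci
  called in both individuals. The denominator is the *sum* of both
  individuals' heterozygote counts (the `--relatedness2` output
  convention), under which self = 0.5 exactly, full sibs ≈ 0.25, half
  sibs ≈ 0.125, and unrelated pairs ≈ 0. Pairs with no shared
  informative loci are NaN with a warning.
- **F<sub>ST</sub>** — Weir–Cockerham θ per locus for two populations,
  genotype-based with the observed-heterozygosity correction, averaged
  over loci with a defined denominator; negative per-locus values are
  retained (dropping them biases the mean upward).

## GO-term summarization

Input is a table of GO terms with per-DEG occurrence counts and 2-D
semantic coordinates produced upstream by a semantic-similarity
reduction (this package does not compute semantic similarity). Terms
are clustered by k-means (10 seeded restarts, best inertia) after a
canonical sort by GO id. k is chosen from the knee of the
within-cluster sum-of-squares curve: both axes are normalized to [0, 1]
and k is the point of maximum perpendicular distance from the chord
joining the endpoints, computed on the **log** WSS curve. The log scale
is what makes the rule find the true cluster count: before the true k
the WSS decline is convex (each extra cluster splits real structure),
and the chord distance on the raw curve peaks in that convex region; on
the log curve the order-of-magnitude drop at the true k dominates. The
rule stays invariant to rescaling the coordinates. Cluster names are the
member term carried by the most DEGs (ties broken alphabetically by GO
id); the dominant word is the modal token of the lowercased,
punctuation-split member names after removing the stop words {of, to,
in, the, and, process, regulation} — the stop-word list is this
package's choice.

## The simulator

`simulate_counts` draws NB counts whose log2 mean is additive in:
per-gene baseline (Normal(5, 1.5) log2 units), log2 library size factor
(Normal(0, 0.25)), ancestry dose a ∈ {0, ½, 1} times a planted effect,
maternal/paternal indicators, a sex indicator, a per-gene cross-date
batch deviate (sd 0.1), and a per-gene-per-family deviate (sd 0.26).
Planted effect magnitudes are Normal(2, 0.5) log2 units floored at
0.25; 75 % of ancestry genes are upregulated in HH by default.
Dispersion defaults to a fixed α = 0.1 (a gamma option exists). The
defaults were set once: family sd 0.26 reproduces a sibling correlation
of ≈ 0.13, and the H-vs-N parental allele-frequency shift of 0.02
yields an HH-vs-NN F<sub>ST</sub> of ≈ 0.009 at 10,000 loci (the
pedigree sampling alone — 30 offspring from 15 families per group —
contributes ≈ 0.008 of that).

`simulate_genotypes` draws four parents per matrix (H/N mother, H/N
father) binomially from pool allele frequencies (base Uniform(0.05,
0.95), H and N pools shifted ±0.01) and transmits alleles Mendelianly,
so full sibs share both parents and different cells of one matrix share
exactly one.

What the simulator does **not** emulate: gene–gene correlation, GC or
length bias, isoform structure, count outliers, linkage between loci,
and realistic dispersion–mean trends. Passing recovery tests on this
generator therefore demonstrates the estimators' correctness under the
assumed model, not robustness to everything real RNA-seq exhibits.

### A known limitation: composition bias at desk scale

Median-of-ratios normalization assumes most genes are not differentially
expressed. Real designs satisfy this easily (a few hundred DEGs among
tens of thousands of genes); a desk-scale simulation that plants 300
strong effects among 2000 genes does not, and the resulting size-factor
error shifts null genes' estimated fold changes slightly away from the
planted direction, inflating the realized FDR among nulls. This is a
property of the normalization convention, not of the GLM. Consequently
direction-bias recovery is evaluated on the planted ancestry genes
(where it is a clean binomial quantity) rather than on raw
n_up/(n_up + n_down), and DEG counts from heavily-planted simulations
should be read as planted genes plus a normalization-driven tail.

## Problem sizes used by the tests and acceptance script

Chosen once as the package's standard desk scale: G = 2000 genes and
the full 120-sample design for calibration and recovery runs; the
ancestry gradient at constraints {1, 10, 20, 30} with 50 replicates;
permutation calibration at G = 200 with R = 100 over 50 repetitions and
power at G = 300 (60 planted) with R = 99; kinship and F<sub>ST</sub> at
10,000 simulated loci.
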