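# Methods

`gepred` implements a two-step genome-enabled prediction analysis of a
quantitative trait in a pedigreed, genotyped population, together with the
synthetic-population generator, quality control, and evaluation design
needed to exercise it end to end at desk scale.

## Step 1: animal model and pre-adjustment

Phenotypes follow the linear mixed ("animal") model

    y = X θ + Z u + W c + e

with fixed effects θ (sex, contemporary group), additive genetic values
u ~ N(0, A σ²_u) where A is the numerator relationship matrix computed from
the pedigree by the tabular method, maternal permanent-environment effects
c ~ N(0, I σ²_c) indexed by each record's dam, and residuals
e ~ N(0, I σ²_e). Records with unknown dam receive their own singleton
maternal level; they are shrunk heavily and do not inform σ²_c.

Variance components are estimated by REML on Henderson's mixed-model
equations. The baseline iteration is EM (monotone in the restricted
likelihood); after a three-iteration warm-up an average-information (AI)
Newton step is attempted each round and accepted only when it does not
decrease the restricted likelihood, with the EM update as fallback.
Convergence requires a relative change below 1e-8 in every active component
(default cap 500 iterations; typical runs converge in 10–15). A component
driven to a negligible share of the total variance (< 1e-3) whose EM update
has stagnated is a boundary estimate: it is frozen ("pinned") and dropped
from the AI update and the convergence test. Without pinning, EM crawls
indefinitely near the boundary because its fixed-point map approaches the
identity there. Components are floored at 1e-6 × Var(y).

A⁻¹ is formed densely; this caps practical pedigrees at a few thousand
animals, which is the intended scale. The restricted log-likelihood is
evaluated from the same Cholesky factorisation via the standard determinant
identity, so EM monotonicity can be asserted in tests.

The pre-adjusted phenotype passed to step 2 is y* = y − Xθ̂ − Wĉ. The
additive genetic signal is deliberately retained — u is what the
marker-based machines are supposed to predict.

Estimability is handled by dropping one reference level per fixed factor;
standard errors of variance components are not computed (downstream stages
use only the point estimates).

## Step 2a: Bayesian whole-genome regression

Both samplers regress y* on column-standardized dosages (sample SD, n−1):

    y* = 1μ + Σ_j z_j a_j + e.

**BRR** puts a_j ~ N(0, σ²_a) with one shared variance; **Bayes Cπ** mixes a
point mass at zero (probability π) with the same Gaussian slab, carries an
inclusion indicator δ_j per marker, and gives π a Uniform(0,1) prior, so
π | δ ~ Beta(#excluded+1, #included+1). σ²_a and σ²_e get scaled
inverse-chi-square hyperpriors; μ is flat.

Hyperprior defaults: v_a = 4.2, and the scale follows the rule
S²_a = σ̃²_a (v_a − 2)/v_a with σ̃²_a = σ̃²_s / ((1 − π) Σ_j p_j(1 − p_j)),
where σ̃²_s is the variance attributed to all markers jointly. The
denominator is implemented exactly in this single-heterozygosity form; a
`het_factor_2` switch provides the more common 2Σp(1−p) variant (the two
differ by a factor 2 and the choice is absorbed by σ̃²_s in practice).
When allele frequencies are unavailable (the model is handed an anonymous
standardized matrix) the denominator is the marker count m, which is the
equivalent rule for unit-variance columns. Unset values resolve at fit
time: σ̃²_s = 0.5 Var(y*), and S²_e is chosen so the prior mode of σ²_e is
0.5 Var(y*) — weakly informative settings in line with common
whole-genome-regression software defaults.

Sampling is single-site Gibbs with running-residual bookkeeping, O(nm) per
sweep, compiled with numba (the update order is fixed, so chains are
bit-reproducible for a given seed). Default chain: 30,000 iterations,
20,000 burn-in, thinning 5 (2,000 retained draws). The Bayes Cπ indicator
is drawn from its marginal full conditional (slab integrated out), the
effect is drawn only for included markers, and the σ²_a update uses the
included-marker count in its degrees of freedom.

Prediction for new individuals standardizes their dosages with the
*training* means/SDs and forms ŷ = μ̄ + Z_new ā from posterior means.

Correctness is anchored three ways: (i) with variances frozen, the
posterior mean must match the closed-form ridge solution (conjugate
oracle); the test statistic whitens the chain by the exact posterior
Cholesky and scales by ESS-based Monte-Carlo errors, aggregated over five
toys, because per-coordinate 3·SE checks are miscalibrated under correlated
MC errors; (ii) π fixed at 0 reproduces the BRR chain exactly (the two
kernels then walk the same random path); (iii) a successive-conditional
("getting it right") run must leave the prior marginal of σ²_a invariant —
run at v_a = 10 because the v_a = 4.2 prior has no finite variance to
compare against.

## Step 2b: multilayer perceptron

A fully connected net maps standardized dosages to y*: ReLU hidden layers,
single linear output, loss L = (y − ô)ᵀ(y − ô) + λ wᵀw with biases
unpenalized. Weights start N(0, 10⁻⁴), biases at 0. Optimisation is
mini-batch Adam (β₁ = 0.9, β₂ = 0.999, lr 10⁻⁴, batch 256 by default);
each batch objective is its residual sum of squares plus the full λ wᵀw
penalty. Dropout uses the *keep*-probability convention (the search grid
includes 1 = no dropout) and inverted scaling, applied to the input and
every hidden layer but never the output, so prediction needs no rescaling
and is deterministic. Early stopping evaluates the tuning-set MSE every 5
epochs and halts after 5 consecutive evaluations without strict
improvement (cap 1,000 epochs), returning the snapshot from the best
evaluation — training can therefore never return weights worse on the
tuning set than the best it observed.

Architecture search draws each hyperparameter independently and uniformly
from fixed grids — depth {1..4}, width {1, 100..1000 by 100, 2000..5000 by
1000} per layer, λ ∈ {0, 0.0025, …, 0.1} (41 points), keep-rate
{0.5..0.9, 1} — trains each candidate, and selects by tuning-set
prediction correlation with ties broken by lower tuning MSE, then draw
order. The printed λ grid we follow contains an obvious transcription
error (0.3000 amid the 0.0025-spaced sequence); the regular 41-point grid
is used. Search runs sequentially; desk-scale configs shrink widths and
candidate counts without touching the grid definition.

## Quality control

Marker filters: MAF ≥ 0.01, call rate ≥ 95%, Hardy–Weinberg 1-df
chi-square goodness-of-fit P ≥ 1e-10 (removals attributed to the first
criterion failed; the kept set is order-invariant). The chi-square test
stands in for an exact test; at the extreme 1e-10 threshold the decisions
coincide for non-degenerate counts. Non-autosomal/unmapped markers are
handled through a caller-supplied exclusion list since no map is
simulated. Surviving missing calls are imputed with the marker's observed
mean dosage (real-valued). Phenotype records beyond ±3.5 SD of their
contemporary-group mean are removed; group statistics include the
candidate record (the natural reading of "average of their group"), with
sample SD, and singleton groups are kept with a warning.

## Evaluation design

The split is chronological: the newest two generations test, the
next-newest generation tunes (used only by the net for early stopping and
architecture selection), everything older trains. Learning curves come
from nested sub-samples — one permutation of the training ids, subset k =
first round(f_k·n/100) ids (round half away from zero), so nesting is
automatic. The Bayesian models are additionally refit "with tuning" (WT:
subset ∪ tuning set) to offset the extra data the net consumes.

Metrics: Pearson correlation of y* with predictions; MSEP = Σ(y*_i −
ŷ_i)²/n_test; relative gain (r₁ − r₂)/r₂ × 100; predictive bias as the OLS
slope of y* on ŷ (1 = unbiased; > 1 means over-shrunk predictions; the
converse regression is available by flag); Spearman correlation between
method predictions (mid-ranks for ties); and top-k agreement, 100·|A∩B|/k
with ties broken by stable id order. k defaults to 10% of the test set
(reported agreement percentages carry one decimal, which a literal top-10
cannot produce); a literal k = 10 is also supported. Within the comparison
harness, a marker that is monomorphic inside a small training subset is
kept as an all-zero standardized column so marker indices stay aligned
with the test set.

## Synthetic populations

The generator emulates the data structure the analysis expects, not any
particular population's genome. Pedigree: discrete non-overlapping
generations; per generation, `n_dams` breeding females and roughly
`n_dams`/9 males (the dam:sire census ratio of commercial broiler
pedigrees) are drawn from the previous generation, and each offspring gets
a random (sire, dam) pair, producing maternal sibships. Contemporary
groups are hatch-batch-like labels nested within generation. Genotypes:
marker frequencies Uniform(maf_range); founders draw Binomial(2, p_j) and
non-founders are gene-dropped (one gamete per parent, free recombination),
so relatives show the A-structured genotype correlation pedigree REML
needs while markers remain mutually independent — there is no linkage
disequilibrium, which no downstream formula uses. Independent-draw and
crude block-copy modes exist for QC tests and stress tests.

Trait construction: a fraction `prop_qtl` (default 0.1) of markers gets
Gaussian effects; breeding values Z_c a, per-dam maternal effects, and
residuals are each rescaled empirically (divide by realized SD) so their
sample variances hit the targets exactly per replicate — defaults h² =
0.23, c² = 0.05, phenotypic variance 18,939.6 g², trait mean 2,141.8 g, a
300 g male−female difference, and 60 g SD contemporary-group effects, a
realistic six-week broiler body-weight setting. Exact per-replicate
variance fractions make recovery tests sharp. Founders receive their own
maternal level so the maternal effect is Gaussian across all records.

What the generator does *not* emulate: LD and marker density of real
chips, selection (parents are drawn at random, so there is no genetic
trend), genotyping error, overlapping generations, or the census sizes of
commercial pedigrees. Passing tests therefore demonstrate correctness of
the estimators and the experimental machinery under the assumed model, not
predictive performance on real broiler data.

## Problem sizes and numerical choices

Checks run at sizes chosen so the whole suite completes on a single CPU in
minutes: REML recovery uses 20–30 replicate populations of 1,500 birds (5
generations, 50 dams each) — the Monte-Carlo SE of the mean ĥ² is ≈ 0.013,
comfortably inside the ±0.03 acceptance band; the Bayes Cπ sparsity study
uses 1,500 individuals × 500 markers with 10 QTL and the full 30,000-cycle
chain; the learning-curve experiment uses five 1,200-bird populations with
a seven-point ladder and shortened BRR chains (4,000/1,500/5), which is
ample for posterior means. Dense-matrix REML is the dominant cost
(~10 s per 1,500-bird fit).

Degenerate inputs are handled explicitly: constant marker columns are a QC
error for the strict standardizer; zero-variance prediction vectors yield
missing correlations; singleton contemporary groups are kept with a
warning; cyclic pedigrees, all-missing markers, empty tuning sets, and
rank-deficient fixed-effect designs raise errors.

## Design choices made where the design was open

- Model objects follow the statsmodels convention (model → `fit()` →
  results with `summary()`); the pipeline module binds them into a CLI for
  shell use.
- The EM/AI hybrid (rather than pure EM or pure Newton) buys robustness
  far from the optimum and fast terminal convergence; the AI step is
  rejected in favour of EM whenever it would reduce the restricted
  likelihood.
- Outlier statistics are group-inclusive rather than leave-one-out; with
  the 3.5 SD threshold and realistic group sizes the two readings almost
  always agree.
- The dropout "rate" is read as keep-probability; a grid containing 1
  admits no other consistent reading given that rate-1 networks train
  without dropout.
- "No improvement" in early stopping means not strictly better than the
  best so far — no tolerance band.
- Sub-sample sizes round half away from zero; top-k ties break by id
  order. Both choices exist purely for determinism.

## Known limitations

- REML is dense-matrix; no sparse-inverse tricks, no single-step H matrix,
  single-trait only.
- The Bayes Cπ sampler offers no convergence diagnostics beyond retained
  draws; multi-chain R-hat is out of scope.
- The MLP is CPU-only NumPy; the full Table-style grid with 5,000-unit
  layers on ~50k inputs is expressible but not practical at desk scale.
- Boundary REML replicates (ĉ² → 0) are a genuine feature of the sampling
  distribution at these population sizes; reported recovery is about the
  mean across replicates.
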