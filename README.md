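# gepred — genome-enabled prediction of complex traits at desk scale

`gepred` is a research pipeline for comparing whole-genome regression and
neural-network predictors of a quantitative trait (the motivating setting
is six-week body weight in a purebred broiler line) on a pedigreed,
SNP-genotyped population. It is aimed at quantitative geneticists who want
a fully inspectable, testable implementation of the standard two-step
analysis — every estimator is written in NumPy/numba and checked against
independent oracles — together with a synthetic-population generator, so
the whole study design runs end to end on a laptop without any proprietary
breeding data.

## The analysis

**Step 1 — pre-adjustment.** Phenotypes follow the animal model

y = Xθ + Zu + Wc + e,  u ~ N(0, A σ²ᵤ),  c ~ N(0, I σ²꜀),  e ~ N(0, I σ²ₑ),

with sex and contemporary group fixed, additive genetic values structured
by the pedigree relationship matrix A, and a dam-associated maternal
permanent-environment term. Variance components are estimated by REML
(EM iterations with average-information acceleration on Henderson's
mixed-model equations); heritability is h² = σ²ᵤ/σ²ₚ and the maternal
fraction c² = σ²꜀/σ²ₚ with σ²ₚ the component sum. The pre-adjusted
phenotype y* = y − Xθ̂ − Wĉ keeps the additive signal and is the response
for step 2.

**Step 2 — marker-based prediction.** Three machines are fit on
standardized SNP dosages: Bayesian Ridge Regression (one shared Gaussian
prior variance across markers), Bayes Cπ (point-mass/Gaussian mixture with
unknown exclusion probability π, Gibbs-sampled with per-marker inclusion
indicators), and a multilayer perceptron (ReLU hidden layers, ridge
penalty, Adam, dropout, tuning-set early stopping, random architecture
search). Evaluation is forward prediction: train on older generations,
tune on the next generation, test on the newest two, across a ladder of
nested training sub-samples, scoring prediction correlation, MSEP,
relative gain, bias slope, Spearman agreement and top-k overlap between
methods.

## Worked example

```python
import pandas as pd
from gepred import SimConfig, simulate_dataset, AnimalModel
from gepred.bayes import McmcConfig
from gepred.evaluate import chronological_split, nested_subsamples, run_comparison

cfg = SimConfig(n_individuals=1200, n_markers=300, n_generations=6,
                n_dams=40, seed=7)
G, pedigree, phenotypes, truth = simulate_dataset(cfg)

fit = AnimalModel.from_dataframe(phenotypes, pedigree).fit()
print(fit.summary())
```

```
Animal model REML results
============================================
records                     1200
fixed effects (p)             49
genetic levels (q)          1200
maternal levels              400
iterations                    11
--------------------------------------------
sigma2_u (additive)      4432.29
sigma2_c (maternal)      1214.43
sigma2_e (residual)     13771.97
phenotypic variance     19418.69
h2                         0.228
c2                         0.063
============================================
```

The population was simulated at h² = 0.23 and c² = 0.05 with a phenotypic
variance of 18,939.6 g²; the REML estimates (0.228 and 0.063 on this
replicate) recover them up to sampling noise. Continuing with the
forward-prediction comparison:

```python
y_star = pd.Series(fit.preadjusted(), index=phenotypes["id"].astype(str))
split = chronological_split(phenotypes)              # newest 2 gens test
ladder = nested_subsamples(split.train_ids, (10, 30, 100), seed=1)
report = run_comparison(y_star, G, split, ladder,
                        methods=("BRR", "BayesCpi"),
                        mcmc=McmcConfig(6000, 2000, 5, seed=2))
print(report.summary())
```

```
Evaluation report
============================================================
Prediction correlation by training fraction (%):
fraction    10     30     100
method                       
BRR      -0.002  0.190  0.278
BayesCpi -0.022  0.216  0.386

MSEP by training fraction (%):
fraction      10       30       100
method                             
BRR       15942.5  15083.9  14252.8
BayesCpi  15949.5  14899.8  13241.3
```

Correlation with the pre-adjusted phenotype rises and MSEP falls as the
training fraction grows — the learning-curve behaviour the sub-sampling
design exists to expose. Bayes Cπ benefits from the sparse simulated
architecture (10% of markers carry effects). A trait dominated by noise
caps the attainable correlation near √h̄² of the test set, so values
around 0.3–0.4 at these sizes are expected, not a defect.

The same pipeline runs from the shell:

```bash
gepred run-all --seed 1 --outdir results/demo          # simulate + full run
gepred simulate --outdir data/                          # just the generator
gepred preadjust --phenotypes data/phenotypes.csv --pedigree data/pedigree.csv
```

`run-all` writes tidy metric tables, wide per-method tables, the QC
report, variance components, the pre-adjusted phenotypes, and a
`manifest.json` that records seeds, versions and per-stage record counts —
enough to relaunch an identical run.

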