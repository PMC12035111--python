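# cutroc

Covariate-aware optimal cutoff estimation for ROC analysis.

Diagnostic biomarkers are turned into decisions through a cutoff: values
on one side of it are called diseased. `cutroc` is for biostatisticians
who need to *choose* that cutoff — and to know how much the choice
depends on how the ROC curve was estimated, and on patient covariates
such as sex or age.

The package implements five ROC estimation models —

- **Emp** — empirical ROC (Mann–Whitney AUC, exhaustive cutoff scan),
- **NonPar** — Gaussian-kernel smoothed CDFs (Silverman bandwidths),
- **BN** — Bayesian binormal model, `ROC(t) = Φ(a + bΦ⁻¹(t))`,
- **PV** — Bayesian parametric placement-value model, which models the
  CDF of `Z = 1 − F0(Y1)` (that CDF *is* the ROC curve),
- **Semi.PV** — a semiparametric PV model with a Dirichlet-process
  mixture for the probit placement values,

— and four optimal-cutoff criteria as functionals of the fitted
distributions: the Youden index `J = se + sp − 1` (maximized), the
closest-to-(0,1) distance `ER = √((1−se)² + (1−sp)²)` (minimized), the
concordance probability `CZ = se·sp` (maximized), and the index of union
`IU = |se − AUC| + |sp − AUC|` (minimized). The BN, PV and Semi.PV
models accept covariates through linear regressions, giving
covariate-specific ROC curves, AUCs and cutoffs (e.g. sex-specific
cutoffs from one fit). Bayesian inference uses conjugate Gibbs /
Metropolis-within-Gibbs sampling with N(0, 100) coefficient and
IG(0.01, 0.01) variance priors; uncertainty for the nonparametric models
comes from a stratified percentile bootstrap.

A simulation engine generates data from a full battery of generating
mechanisms (binormal, squared-normal, log-normal, gamma, normal
mixtures, with and without covariates), recomputes exact truths with an
analytic oracle, and summarizes estimator bias as median ± IQR across
replicates. See `docs/methods.md` for models, priors and numerical
choices.

## Worked example

```python
import numpy as np, pandas as pd
from cutroc import validate_sample, bn_fit, empirical_auc, empirical_cutoffs, MCMCSettings

rng = np.random.default_rng(0)
n = 150
df = pd.DataFrame({
    "biomarker": np.r_[rng.normal(0.0, 1.0, n), rng.normal(1.2, 1.0, n)],
    "status":    np.r_[np.zeros(n, int), np.ones(n, int)],
})
sample = validate_sample(df, direction="higher")

print("empirical AUC:", round(empirical_auc(sample.y0, sample.y1), 3))
cuts = empirical_cutoffs(sample)
print("empirical Youden cutoff:", round(cuts["J"].cutoff, 3),
      "(se=%.2f, sp=%.2f)" % (cuts["J"].sensitivity, cuts["J"].specificity))

fit = bn_fit(sample, mcmc=MCMCSettings(), seed=1)
s = fit.summary()
print("BN posterior AUC: %.3f (95%% CI %.3f-%.3f)" % s.auc)
for k in ("J", "ER", "CZ", "IU"):
    print("BN %-2s cutoff: %.3f (95%% CI %.3f-%.3f)" % ((k,) + s.cutoffs[k]))
```

prints

```
empirical AUC: 0.752
empirical Youden cutoff: 0.412 (se=0.74, sp=0.65)
BN posterior AUC: 0.756 (95% CI 0.700-0.806)
BN J  cutoff: 0.644 (95% CI 0.476-0.814)
BN ER cutoff: 0.571 (95% CI 0.455-0.685)
BN CZ cutoff: 0.591 (95% CI 0.470-0.711)
BN IU cutoff: 0.634 (95% CI 0.477-0.773)
```

The data were drawn with a true AUC of Φ(1.2/√2) ≈ 0.80 and, because the
two groups share a variance, a common true cutoff of 0.6 for all four
criteria. The empirical scan lands where the finite-sample criterion
surface happens to peak (0.41), while the binormal posterior means
cluster near the truth with honest 95% intervals — the spread between
criteria and between models at n = 150 is exactly the phenomenon the
package is built to quantify.

With covariates (e.g. a `sex` column), fit `bn_fit(sample,
use_covariates=True)` and call `covariate_specific_summary(fit, [0, 1])`
for per-group AUCs and cutoffs from one posterior.

## Command line

```bash
cutroc fit --csv data.csv --models emp,nonpar,bn,pv,semipv \
           --direction higher --covariates sex --at 0,1 --seed 1 --out report/
cutroc simulate --scenarios BN_unequal:medium,Skewed_II:low \
                --models emp,bn,pv --n-reps 1000 --seed 1 --out sim/
```

`fit` writes `fit_report.json`/`fit_report.csv` (AUC and four cutoffs
with 95% intervals, one block per covariate value; `--plot` adds a
density-plus-cutoffs figure). `simulate` writes `bias_table.csv`
(median and IQR of estimate − truth per scenario, model and metric).

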