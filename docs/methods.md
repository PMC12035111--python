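# Methods

`cutroc` estimates covariate-aware optimal biomarker cutoffs from ROC
analysis. This note records the models, the numerical choices, and the
design decisions where more than one reasonable option existed.

## Setting and notation

Biomarker values `Y0 ~ F0` (healthy) and `Y1 ~ F1` (diseased) are compared
through the ROC curve `ROC(t) = 1 − F1(F0⁻¹(1 − t))` and its area
`AUC = ∫₀¹ ROC(t) dt`. At a cutoff `c`, sensitivity is
`se(c) = 1 − F1(c)` and specificity `sp(c) = F0(c)`. The working
convention everywhere is that higher biomarker values indicate disease;
biomarkers that run the other way (e.g. CSF amyloid-β, where low values
flag Alzheimer's disease) are negated on input and every reported cutoff
is negated back.

Four cutoff criteria are implemented:

| criterion | objective | direction |
|---|---|---|
| Youden index (J) | `se + sp − 1` | maximize |
| Closest-to-(0,1) (ER) | `√((1−se)² + (1−sp)²)` | minimize |
| Concordance probability (CZ) | `se · sp` | maximize |
| Index of union (IU) | `|se − AUC| + |sp − AUC|` | minimize |

IU is always evaluated against the *same model's* AUC estimate (per-draw
AUC inside MCMC), since the criterion couples the cutoff to the model's
accuracy summary. When several cutoffs minimize IU within 1e−9, the one
minimizing `|se − sp|` is preferred (the criterion's secondary rule),
switchable off via `iu_secondary=False`.

## The placement-value view

The placement value `Z = 1 − F0(Y1)` standardizes a diseased score
against the healthy distribution; its CDF *is* the ROC curve. The PV
parameterization rewrites sensitivity as `se(c) = F(1 − F0(c))` with `F`
the PV CDF, so a model of `(F0, F)` is an equivalent route to cutoffs.
For a normal `F0` and a probit link, `Φ⁻¹(Z) = −(Y1 − μ0)/σ0`, so the
probit-normal PV model is an exact reparameterization of the binormal
model — the package exploits this identity both for computation and for
cross-checking the two model families against each other.

## Estimators

**Empirical (Emp).** Mann–Whitney AUC (ties count one half), which equals
the trapezoid area under the empirical ROC exactly. Cutoff criteria are
constant between observations, so the optimum is found by exhaustive scan
over the midpoints of consecutive pooled order statistics, padded by one
candidate below the minimum and one above the maximum. Among exact ties
the smallest cutoff wins (determinism across platforms).

**Kernel-smoothed (NonPar).** Gaussian-kernel CDFs per group with
Silverman's rule-of-thumb bandwidth `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`
computed separately for each group. The kernel CDF is strictly
increasing; its quantile is computed by vectorized bisection plus Newton
polish, exact to ~1e−12. Both nonparametric models refuse covariates.

**Confidence intervals for Emp/NonPar** come from a stratified percentile
bootstrap (resampling within each group, preserving group sizes; 2.5/97.5
percentiles; 1000 replicates by default). Percentile rather than BCa,
matching the plain 95% intervals the method is usually reported with.

**Bayesian binormal (BN).** One normal linear regression per disease
group (intercept-only without covariates), conjugate Gibbs sampling:
multivariate-normal coefficient update given the variance, inverse-gamma
variance update given the coefficients. Priors: N(0, 100) on every
coefficient, IG(0.01, 0.01) on every variance. Per retained draw,
`a_x = (β01−β00 + (β11−β10)x)/σ1`, `b = σ0/σ1`,
`AUC_x = Φ(a_x/√(1+b²))`, and the four cutoffs are optimized on that
draw's two normal CDFs. Point estimates are posterior means of the
metrics themselves (not plug-ins at posterior-mean parameters), with
2.5/97.5 posterior percentiles as 95% credible intervals; medians are
available via `point_estimate="median"`.

**Parametric placement-value (PV).** Normal regression for the healthy
group; probit-transformed placement values of the diseased group follow a
second normal regression (`w = Φ⁻¹(z) ~ N(β0 + β1 x, σ²)`). The default
is a *two-stage plug-in* sampler: healthy parameters are drawn from their
own conjugate posterior, the placement values are recomputed per draw,
and the PV-regression parameters are updated conjugately. A fully joint
alternative (`two_stage=False`) updates the healthy parameters by
random-walk Metropolis with the diseased data entering through the exact
change of variables `y1 → w` (Jacobian `1/σ0` for normal `F0`), with
proposal scales adapted toward 20–40% acceptance during burn-in.

The plug-in default is deliberate. On well-specified (binormal) data the
two variants are indistinguishable. Under misspecification they are not:
the joint likelihood lets the diseased group pull the healthy fit, which
changes covariate-specific AUC by ≈0.07 on the covariate gamma scenario —
and the plug-in variant is the one whose bias profile matches the
behaviour reported for this model family in the cutoff-estimation
literature. The trade-off is that plug-in
intervals do not propagate healthy-parameter uncertainty into the PV
regression likelihood and can be slightly narrow.

Placement values are clamped to [1e−6, 1−1e−6] before the probit
transform (prevents infinite transforms; occurrences are logged).
Per-draw AUC is the trapezoid integral of `ROC_x(t) = Φ((Φ⁻¹(t) −
β0 − β1x)/σ)` on a 2001-point grid.

**Semiparametric placement-value (Semi.PV).** Healthy group as in PV;
the probit placement values follow a truncated Dirichlet-process mixture
of normals via stick-breaking (default truncation H = 20, concentration
α = 1), with a shared linear covariate shift on the atoms in the
covariate case. Blocked Gibbs: multinomial allocations, conjugate
component means/variances (base measure matching the parametric priors:
N(0, 100) and IG(0.01, 0.01)), Beta stick updates, conjugate slope, and a
Metropolis step for the healthy parameters against the mixture
likelihood. Label switching is left unhandled on purpose: every reported
quantity is a functional of the mixture CDF, which is invariant to
relabelling. The mixture AUC uses the exact decomposition
`AUC = Σ_h w_h Φ(−(m_h + β1 x)/√(1 + s_h²))` (the ROC is linear in the
components). Component standard deviations drawn from the nearly
improper base measure for empty components are clipped to [1e−2, 1e2] as
a numerical guard.

With one active component (H = 1) Semi.PV reproduces the parametric PV
model; on unimodal data its estimates track BN/PV closely. On skewed
data the mixture adapts where the parametric PV is misspecified; in this
implementation that makes Semi.PV cutoff estimates *less* variable across
replicates than PV's on log-normal data (e.g. Youden-cutoff IQR 0.94 vs
2.53 at N=100 on the low-AUC log-normal scenario), not more — flexible-F
implementations that also model F0 nonparametrically can show the
opposite ranking.

## MCMC layout and diagnostics

Full analyses default to 2 chains × 10 000 iterations, 5 000 burn-in,
thinned to exactly 5 000 retained draws in total. Convergence is
monitored by split-R̂ per parameter with threshold 1.1; failure flags the
fit summary rather than raising (split-R̂ of identical chains is ≈0.9995,
not exactly 1, because of the (n−1)/n pooled-variance shrinkage).
Simulation studies use a cheaper single-chain default (3 000 iterations,
1 000 burn-in, 2 000 retained; `full_mcmc=True` restores the full
layout) — bias medians are insensitive to chain length.

## Cutoff optimizer

Continuous fits use a deterministic dense grid (default 2001 points over
the pooled 0.001–0.999 quantile range) plus golden-section refinement
inside the best grid cell to 1e−6; exact ties resolve to the smallest
cutoff; a criterion surface flat within 1e−9 over the whole range sets
`degenerate_flag`. Inside MCMC, cutoffs for thousands of draws are
computed by a vectorized three-round zoom grid (81 points per round,
resolution ≈1.6e−5 of the search range), equivalent to grid-plus-refine
for these smooth unimodal surfaces. The oracle for simulation truths
uses a 1e6-point scan plus golden-section refinement; truths are
insensitive to grid density beyond ~1e5 points.

## Synthetic data generators

The simulation module implements the generating mechanisms of the
reference bias study literally: equal/unequal binormal; squared-normal ("square-root
scale normal": `Y = W²`, `W ~ N(μ, σ²)`); log-normal; gamma
(shape/scale); and "mixed" mechanisms whose diseased (and for Mixed II
healthy) law is written as a *single* normal with combined moments
`πμ₁ + (1−π)μ₂` and `π²σ₁² + (1−π)²σ₂²`. That literal single-normal
reading is the default because the reference bias results for these rows
behave exactly like a well-specified binormal (near-zero BN bias), which
only the literal reading produces; `mixture_literal=False` draws from the
genuine two-component mixture instead for sensitivity analysis.
Covariate scenarios draw `X ~ Uniform(−0.5, 1.5)` independently per
group, with normal regressions, gamma scale regressions, or combined
normal-mean regressions on `X`; in the covariate mixed mechanism both
diseased component means depend on the diseased covariate `X1` (a
diseased outcome cannot depend on an unobserved healthy covariate).

The generators emulate the study conditions, not real data: groups have
equal sizes (50% prevalence), covariate effects are linear, and there is
no measurement error, missingness, or verification bias. Passing the
bias study therefore demonstrates estimator correctness under these
laws, not robustness to the complications of applied biomarker data.

Truths (AUC, cutoffs) are recomputed analytically: closed forms for the
normal-based and equal-shape gamma AUCs (`AUC = 1 − F_Beta(k,k)(θ0/(θ0+θ1))`),
the log-scale normal closed form for log-normal AUC (AUC is invariant
under increasing transforms), numeric integration otherwise, and the
1e6-point oracle scan for cutoffs.

## Bias study

For each (scenario, model) cell: replicate r uses seed `seed₀ + r`
(results independent of execution order), generates N per group
(default 100), fits, takes the point estimate (posterior mean for
Bayesian models, direct estimate otherwise), and subtracts the oracle
truth; the cell reports median and IQR of the biases with type-7
(linear-interpolation) quantiles. The bias sign convention is
`estimate − truth` (positive = overestimation), flippable via
`bias_sign`. Replicate failures are logged and excluded, never fatal;
a fully failed cell is reported as missing.

The acceptance script reruns selected cells at N=100 with 1000
replicates for the non-Bayesian models and 200 replicates with the
reduced MCMC for the Bayesian ones — these sizes keep a full rerun
within minutes on one core while leaving the median-bias Monte Carlo
error well below the reporting tolerances.

## Known limitations

- Two-class problems only; no time-dependent ROC, no ROC surfaces.
- Linear covariate effects only; more than one covariate is accepted by
  the design matrices but exercised only lightly.
- The empirical and kernel models cannot accommodate covariates.
- Plug-in PV intervals can understate healthy-parameter uncertainty (see
  above); the joint sampler is available when that matters.
- Semi.PV keeps a parametric healthy distribution; only the PV law is
  flexible. Data whose *healthy* group is itself multimodal will push
  the mixture to compensate through the PV law.
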