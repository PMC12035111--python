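"""Bayesian binormal and parametric placement-value ROC models.

Both models describe each group (or its placement values) with normal
linear regressions.  Inference is by MCMC with conjugate Gibbs updates
where the full conditionals are available and a Gaussian random-walk
Metropolis step for the healthy-group parameters of the joint
placement-value model, whose likelihood also involves the diseased data
through the placement values.

Priors follow the common objective choice: N(0, 100) on every regression
coefficient and IG(0.01, 0.01) on every variance.  Derived quantities
(AUC and the four optimal cutoffs) are computed per retained draw, so the
reported posterior means and 95% credible intervals refer to the metrics
themselves rather than to a plug-in at the posterior-mean parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .criteria import Criterion
from .data_model import BiomarkerSample, Direction

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "PosteriorDraws",
    "FitSummary",
    "gibbs_normal_regression",
    "gelman_rubin",
    "bn_fit",
    "pv_fit",
    "covariate_specific_summary",
]

_CRITERIA = [c.value for c in Criterion]
_PV_CLAMP = 1e-6
_RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class PriorSpec:
    """N(mean, variance) on coefficients, IG(shape, rate) on variances."""

    coef_mean: float = 0.0
    coef_variance: float = 100.0
    var_shape: float = 0.01
    var_rate: float = 0.01


@dataclass(frozen=True)
class MCMCSettings:
    """Chain layout. Defaults: 2 chains of 10k iterations, half burn-in,
    thinned so that exactly ``n_retained`` draws are kept in total."""

    n_iter: int = 10_000
    n_burn: int = 5_000
    n_chains: int = 2
    n_retained: int = 5_000

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")
        kept = (self.n_iter - self.n_burn) * self.n_chains
        if kept < self.n_retained:
            raise ValueError("not enough post-burn-in iterations to retain")

    @classmethod
    def reduced(cls) -> "MCMCSettings":
        """Cheaper settings for simulation studies (bias medians are
        insensitive to chain length; runtime is not)."""
        return cls(n_iter=3_000, n_burn=1_000, n_chains=1, n_retained=2_000)


@dataclass
class PosteriorDraws:
    """Retained draws (parameters + per-draw derived metrics) and diagnostics."""

    draws: pd.DataFrame
    n_chains: int
    rhat: dict[str, float]
    seed: int
    chain_index: np.ndarray = field(repr=False, default=None)

    @property
    def converged(self) -> bool:
        return all(r < _RHAT_THRESHOLD for r in self.rhat.values())


@dataclass(frozen=True)
class FitSummary:
    """Posterior point estimates with 95% credible intervals."""

    auc: tuple[float, float, float]
    cutoffs: dict[str, tuple[float, float, float]]
    point_estimate: str = "mean"
    converged: bool = True
    at_x: float | None = None


def _summ(values: np.ndarray, point_estimate: str) -> tuple[float, float, float]:
    point = float(np.mean(values) if point_estimate == "mean" else np.median(values))
    lo, hi = np.percentile(values, [2.5, 97.5])
    return point, float(lo), float(hi)


def gibbs_normal_regression(
    y: np.ndarray,
    design: np.ndarray,
    priors: PriorSpec = PriorSpec(),
    n_iter: int = 10_000,
    n_burn: int = 5_000,
    n_chains: int = 2,
    seed: int = 0,
) -> list[np.ndarray]:
    """Conjugate Gibbs sampler for normal linear regression.

    Alternates the exact full conditionals: multivariate normal for the
    coefficient vector given the variance, inverse-gamma for the variance
    given the coefficients.  Returns one array per chain of shape
    (n_iter - n_burn, p + 1) holding the coefficients and the variance.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if n_iter <= n_burn:
        raise ValueError("n_iter must exceed n_burn")
    XtX = X.T @ X
    Xty = X.T @ y
    prior_prec = np.eye(p) / priors.coef_variance
    prior_mean_term = prior_prec @ np.full(p, priors.coef_mean)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    sigma2_init = max(float(resid @ resid) / max(n - p, 1), 1e-8)

    ss = np.random.SeedSequence(seed)
    chains = []
    for chain_seed in ss.spawn(n_chains):
        rng = np.random.default_rng(chain_seed)
        beta = beta_ols.copy()
        sigma2 = sigma2_init
        out = np.empty((n_iter - n_burn, p + 1))
        for it in range(n_iter):
            prec = XtX / sigma2 + prior_prec
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(
                prec, Xty / sigma2 + prior_mean_term
            )
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)
            r = y - X @ beta
            shape = priors.var_shape + 0.5 * n
            rate = priors.var_rate + 0.5 * float(r @ r)
            sigma2 = rate / rng.gamma(shape)
            if it >= n_burn:
                out[it - n_burn, :p] = beta
                out[it - n_burn, p] = sigma2
        chains.append(out)
    return chains


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Split-R-hat convergence statistic for one scalar parameter."""
    arr = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(arr) < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    n = min(a.size for a in arr)
    if n < 10 or any(a.size != n for a in arr):
        raise ValueError("chains must have equal lengths of at least 10")
    half = n // 2
    split = []
    for a in arr:
        split.append(a[:half])
        split.append(a[half : 2 * half])
    split = np.asarray(split)
    m, nn = split.shape
    chain_means = split.mean(axis=1)
    within = split.var(axis=1, ddof=1).mean()
    between_over_n = chain_means.var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (nn - 1) / nn * within + between_over_n
    return float(np.sqrt(var_plus / within))


def _thin_chains(chains: list[np.ndarray], n_retained: int) -> tuple[np.ndarray, np.ndarray]:
    """Evenly thin post-burn-in chains down to n_retained total rows."""
    per_chain = n_retained // len(chains)
    extra = n_retained - per_chain * len(chains)
    rows, chain_idx = [], []
    for k, c in enumerate(chains):
        take = per_chain + (1 if k < extra else 0)
        idx = np.linspace(0, c.shape[0] - 1, take).round().astype(int)
        rows.append(c[idx])
        chain_idx.append(np.full(take, k))
    return np.concatenate(rows), np.concatenate(chain_idx)


# ---------------------------------------------------------------------------
# Vectorized per-draw cutoff search
# ---------------------------------------------------------------------------


def _criterion_loss(crit: Criterion, se, sp, auc):
    if crit is Criterion.J:
        return -(se + sp - 1.0)
    if crit is Criterion.ER:
        return (1.0 - se) ** 2 + (1.0 - sp) ** 2
    if crit is Criterion.CZ:
        return -(se * sp)
    return np.abs(se - auc[:, None]) + np.abs(sp - auc[:, None])


def _zoom_cutoffs(se_of, sp_of, lo, hi, auc, n_pts=81, n_rounds=3):
    """Per-draw criterion optimization by iterative grid refinement.

    ``se_of(c)`` / ``sp_of(c)`` map a (draws, grid) cutoff matrix to
    operating characteristics.  Three rounds of an 81-point grid give a
    resolution of about (hi-lo) * 1.6e-5, ample for posterior summaries.
    """
    out = {}
    base = np.linspace(0.0, 1.0, n_pts)
    for crit in Criterion:
        clo, chi = lo.copy(), hi.copy()
        for _ in range(n_rounds):
            cand = clo[:, None] + (chi - clo)[:, None] * base
            loss = _criterion_loss(crit, se_of(cand), sp_of(cand), auc)
            idx = np.argmin(loss, axis=1)
            step = (chi - clo) / (n_pts - 1)
            center = cand[np.arange(cand.shape[0]), idx]
            clo = center - step
            chi = center + step
        out[crit.value] = 0.5 * (clo + chi)
    return out


def _normal_draw_cutoffs(mu0, s0, mu1, s1, auc):
    lo = np.minimum(mu0 - 5 * s0, mu1 - 5 * s1)
    hi = np.maximum(mu0 + 5 * s0, mu1 + 5 * s1)
    se_of = lambda c: 1.0 - ndtr((c - mu1[:, None]) / s1[:, None])
    sp_of = lambda c: ndtr((c - mu0[:, None]) / s0[:, None])
    return _zoom_cutoffs(se_of, sp_of, lo, hi, auc)


def _pv_draw_cutoffs(mu0, s0, muz, sz, auc):
    """Cutoffs under the PV parameterization with normal F0 and probit-normal F.

    se(c) = F(1 - F0(c)) with F the PV CDF; for the probit link this equals
    Phi((-(c - mu0)/s0 - muz) / sz) exactly.
    """
    lo = np.minimum(mu0 - 5 * s0, mu0 - (muz + 5 * sz) * s0)
    hi = np.maximum(mu0 + 5 * s0, mu0 - (muz - 5 * sz) * s0)
    se_of = lambda c: ndtr(
        (-(c - mu0[:, None]) / s0[:, None] - muz[:, None]) / sz[:, None]
    )
    sp_of = lambda c: ndtr((c - mu0[:, None]) / s0[:, None])
    return _zoom_cutoffs(se_of, sp_of, lo, hi, auc)


def _pv_draw_auc(muz, sz, n_grid=2001):
    """Per-draw trapezoid AUC of ROC(t) = Phi((Phi^-1(t) - muz) / sz)."""
    t = np.arange(1, n_grid + 1) / (n_grid + 1.0)
    q = ndtri(t)
    r = ndtr((q - muz[:, None]) / sz[:, None])
    t_full = np.concatenate([[0.0], t, [1.0]])
    r_full = np.concatenate(
        [np.zeros((r.shape[0], 1)), r, np.ones((r.shape[0], 1))], axis=1
    )
    return np.trapezoid(r_full, t_full, axis=1)


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------


def _design(x: np.ndarray | None, n: int, use_covariates: bool) -> np.ndarray:
    if not use_covariates or x is None:
        return np.ones((n, 1))
    return np.column_stack([np.ones(x.shape[0]), x])


def _check_covariates(sample: BiomarkerSample, use_covariates: bool) -> None:
    if use_covariates and not sample.has_covariates:
        raise ValueError(
            "covariate fit requested but the sample has no covariates; "
            "missing covariates are an error, never silently imputed"
        )


def _back_transform_cutoffs(
    draws: pd.DataFrame, sample: BiomarkerSample
) -> pd.DataFrame:
    """Negate cutoff draws for lower-is-diseased biomarkers (AUC unchanged)."""
    if sample.direction is Direction.lower_is_diseased:
        for col in draws.columns:
            if col.startswith("c"):
                draws[col] = -draws[col]
    return draws


@dataclass
class BayesFit:
    """A fitted Bayesian ROC model: parameter draws plus derived metrics."""

    model: str
    posterior: PosteriorDraws
    sample: BiomarkerSample
    use_covariates: bool
    point_estimate: str = "mean"

    def derived(self, x: float | None = None) -> pd.DataFrame:
        """Per-draw AUC and cutoffs, optionally at covariate value ``x``."""
        d = self.posterior.draws
        if self.use_covariates:
            if x is None:
                raise ValueError("covariate fit: specify the covariate value x")
            mu0 = d["beta00"].to_numpy() + d["beta10"].to_numpy() * x
            if self.model == "bn":
                mu1 = d["beta01"].to_numpy() + d["beta11"].to_numpy() * x
            else:
                muz = d["beta0"].to_numpy() + d["beta1"].to_numpy() * x
        else:
            mu0 = d["beta00"].to_numpy()
            if self.model == "bn":
                mu1 = d["beta01"].to_numpy()
            else:
                muz = d["beta0"].to_numpy()
        s0 = d["sigma0"].to_numpy()
        if self.model == "bn":
            s1 = d["sigma1"].to_numpy()
            a = (mu1 - mu0) / s1
            b = s0 / s1
            auc = ndtr(a / np.sqrt(1.0 + b * b))
            cuts = _normal_draw_cutoffs(mu0, s0, mu1, s1, auc)
        else:
            sz = d["sigma"].to_numpy()
            auc = _pv_draw_auc(muz, sz)
            cuts = _pv_draw_cutoffs(mu0, s0, muz, sz, auc)
        out = pd.DataFrame({"auc": auc})
        for k in _CRITERIA:
            out[f"c{k}"] = cuts[k]
        return _back_transform_cutoffs(out, self.sample)

    def summary(self, x: float | None = None) -> FitSummary:
        der = self.derived(x)
        return FitSummary(
            auc=_summ(der["auc"].to_numpy(), self.point_estimate),
            cutoffs={
                k: _summ(der[f"c{k}"].to_numpy(), self.point_estimate)
                for k in _CRITERIA
            },
            point_estimate=self.point_estimate,
            converged=self.posterior.converged,
            at_x=x,
        )


def _rhat_map(chains: list[np.ndarray], names: list[str]) -> dict[str, float]:
    if len(chains) < 2:
        # single-chain runs: split the one chain in two halves
        c = chains[0]
        half = c.shape[0] // 2
        chains = [c[:half], c[half : 2 * half]]
    return {
        name: gelman_rubin([c[:, j] for c in chains]) for j, name in enumerate(names)
    }


def bn_fit(
    sample: BiomarkerSample,
    use_covariates: bool = False,
    priors: PriorSpec = PriorSpec(),
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    point_estimate: str = "mean",
) -> BayesFit:
    """Bayesian binormal model: one normal regression per disease group.

    Without covariates this is the intercept-only special case.  Per
    retained draw the binormal parameters a = (mu1 - mu0)/sigma1 and
    b = sigma0/sigma1 give AUC = Phi(a / sqrt(1 + b^2)); the cutoffs are
    optimized per draw on the two normal CDFs.
    """
    _check_covariates(sample, use_covariates)
    mcmc = mcmc or MCMCSettings()
    X0 = _design(sample.x0, sample.n0, use_covariates)
    X1 = _design(sample.x1, sample.n1, use_covariates)
    ss = np.random.SeedSequence(seed)
    s0, s1 = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    chains0 = gibbs_normal_regression(
        sample.y0, X0, priors, mcmc.n_iter, mcmc.n_burn, mcmc.n_chains, s0
    )
    chains1 = gibbs_normal_regression(
        sample.y1, X1, priors, mcmc.n_iter, mcmc.n_burn, mcmc.n_chains, s1
    )
    names0 = ["beta00", "beta10"][: X0.shape[1]] + ["var0"]
    names1 = ["beta01", "beta11"][: X1.shape[1]] + ["var1"]
    rhat = _rhat_map(chains0, names0) | _rhat_map(chains1, names1)
    kept0, chain_idx = _thin_chains(chains0, mcmc.n_retained)
    kept1, _ = _thin_chains(chains1, mcmc.n_retained)
    draws = pd.DataFrame(kept0[:, :-1], columns=names0[:-1])
    draws["sigma0"] = np.sqrt(kept0[:, -1])
    for j, name in enumerate(names1[:-1]):
        draws[name] = kept1[:, j]
    draws["sigma1"] = np.sqrt(kept1[:, -1])
    if not all(r < _RHAT_THRESHOLD for r in rhat.values()):
        logger.warning("bn_fit: convergence flagged, max rhat=%.3f", max(rhat.values()))
    posterior = PosteriorDraws(
        draws=draws, n_chains=mcmc.n_chains, rhat=rhat, seed=seed, chain_index=chain_idx
    )
    fit = BayesFit("bn", posterior, sample, use_covariates, point_estimate)
    if not use_covariates:
        der = fit.derived()
        for col in der.columns:
            draws[col] = der[col].to_numpy()
    return fit


def pv_fit(
    sample: BiomarkerSample,
    use_covariates: bool = False,
    priors: PriorSpec = PriorSpec(),
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    point_estimate: str = "mean",
    two_stage: bool = True,
) -> BayesFit:
    """Bayesian parametric placement-value model.

    The healthy group follows a normal regression; the probit-transformed
    placement values of the diseased group follow a second normal
    regression.  By default the healthy parameters are drawn from their
    own conjugate posterior and propagated into the placement values
    (two-stage plug-in).
    With ``two_stage=False`` the healthy parameters are instead updated by
    a random-walk Metropolis step whose likelihood includes the diseased
    data through the placement values — the fully joint model, which under
    misspecification lets the diseased data distort the healthy fit.
    """
    _check_covariates(sample, use_covariates)
    mcmc = mcmc or MCMCSettings()
    y0, y1 = sample.y0, sample.y1
    X0 = _design(sample.x0, sample.n0, use_covariates)
    X1z = _design(sample.x1, sample.n1, use_covariates)  # for mu0 at x1
    Xz = X1z  # design of the PV regression itself
    p0, pz = X0.shape[1], Xz.shape[1]
    names = (
        ["beta00", "beta10"][:p0]
        + ["sigma0"]
        + ["beta0", "beta1"][:pz]
        + ["sigma"]
    )

    XtXz = Xz.T @ Xz
    prior_prec_z = np.eye(pz) / priors.coef_variance
    XtX0 = X0.T @ X0
    Xty0 = X0.T @ y0
    prior_prec_0 = np.eye(p0) / priors.coef_variance
    gamma_ols, *_ = np.linalg.lstsq(X0, y0, rcond=None)
    resid0 = y0 - X0 @ gamma_ols
    sigma0_init = float(np.sqrt(max(resid0 @ resid0 / max(y0.size - p0, 1), 1e-8)))

    def healthy_base(gamma, log_s0):
        """Log-posterior terms depending only on the healthy parameters,
        plus the probit placement values w and a clamp count.

        The diseased contribution uses the exact change of variables
        y1 -> w = Phi^-1(1 - F0(y1)) with Jacobian phi(std1)/(s0 phi(w)).
        """
        s0 = np.exp(log_s0)
        r0 = y0 - X0 @ gamma
        lp = -y0.size * log_s0 - 0.5 * float(r0 @ r0) / s0**2
        std1 = (y1 - X1z @ gamma) / s0
        z = 1.0 - ndtr(std1)
        nc = int(np.sum((z < _PV_CLAMP) | (z > 1.0 - _PV_CLAMP)))
        z = np.clip(z, _PV_CLAMP, 1.0 - _PV_CLAMP)
        w = ndtri(z)
        lp += float(np.sum(-0.5 * std1**2 + 0.5 * w**2)) - y1.size * log_s0
        # priors: normal on gamma, IG on s0^2 (with log-scale Jacobian)
        lp += -0.5 * float(gamma @ gamma) / priors.coef_variance
        lp += (
            -2.0 * priors.var_shape * log_s0
            - priors.var_rate / s0**2
            + 2.0 * log_s0
        )
        return lp, w, nc

    def pv_term(w, beta_z, sig2_z):
        rz = w - Xz @ beta_z
        return -0.5 * float(rz @ rz) / sig2_z - 0.5 * y1.size * np.log(sig2_z)

    ss = np.random.SeedSequence(seed)
    chain_arrays = []
    clamp_total = 0
    for chain_seed in ss.spawn(mcmc.n_chains):
        rng = np.random.default_rng(chain_seed)
        gamma = gamma_ols.copy()
        log_s0 = float(np.log(sigma0_init))
        beta_z = np.zeros(pz)
        sig2_z = 1.0
        scale = 0.1 * np.ones(p0 + 1)
        accepted = proposed = 0
        base, w, _ = healthy_base(gamma, log_s0)
        out = np.empty((mcmc.n_iter - mcmc.n_burn, p0 + 1 + pz + 1))
        for it in range(mcmc.n_iter):
            if two_stage:
                # plug-in variant: healthy parameters from their own
                # conjugate posterior, ignoring the diseased likelihood
                s0sq = np.exp(2 * log_s0)
                prec0 = XtX0 / s0sq + prior_prec_0
                chol0 = np.linalg.cholesky(prec0)
                mean0 = np.linalg.solve(prec0, Xty0 / s0sq)
                gamma = mean0 + np.linalg.solve(chol0.T, rng.standard_normal(p0))
                r0 = y0 - X0 @ gamma
                s0sq = (priors.var_rate + 0.5 * float(r0 @ r0)) / rng.gamma(
                    priors.var_shape + 0.5 * y0.size
                )
                log_s0 = 0.5 * float(np.log(s0sq))
                base, w, _ = healthy_base(gamma, log_s0)
            else:
                # --- Metropolis update of (gamma, log sigma0) ---
                step = rng.standard_normal(p0 + 1) * scale
                gamma_prop = gamma + step[:p0]
                log_s0_prop = log_s0 + step[p0]
                base_prop, w_prop, nc = healthy_base(gamma_prop, log_s0_prop)
                lp_cur = base + pv_term(w, beta_z, sig2_z)
                lp_prop = base_prop + pv_term(w_prop, beta_z, sig2_z)
                proposed += 1
                if np.log(rng.uniform()) < lp_prop - lp_cur:
                    gamma, log_s0, base, w = gamma_prop, log_s0_prop, base_prop, w_prop
                    accepted += 1
                    clamp_total += nc
                # adapt proposal scale during burn-in toward 20-40% acceptance
                if it < mcmc.n_burn and proposed % 100 == 0:
                    rate = accepted / proposed
                    if rate < 0.20:
                        scale *= 0.8
                    elif rate > 0.40:
                        scale *= 1.25
                    accepted = proposed = 0
            # --- conjugate update of PV regression (beta_z, sig2_z) ---
            prec = XtXz / sig2_z + prior_prec_z
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Xz.T @ w / sig2_z)
            beta_z = mean + np.linalg.solve(chol.T, rng.standard_normal(pz))
            rz = w - Xz @ beta_z
            sig2_z = (priors.var_rate + 0.5 * float(rz @ rz)) / rng.gamma(
                priors.var_shape + 0.5 * y1.size
            )
            if it >= mcmc.n_burn:
                row = it - mcmc.n_burn
                out[row, :p0] = gamma
                out[row, p0] = np.exp(log_s0)
                out[row, p0 + 1 : p0 + 1 + pz] = beta_z
                out[row, -1] = np.sqrt(sig2_z)
        chain_arrays.append(out)
    if clamp_total:
        logger.info("pv_fit: clamped %d placement values to (%g, 1-%g)",
                    clamp_total, _PV_CLAMP, _PV_CLAMP)
    rhat = _rhat_map(chain_arrays, names)
    kept, chain_idx = _thin_chains(chain_arrays, mcmc.n_retained)
    draws = pd.DataFrame(kept, columns=names)
    if not all(r < _RHAT_THRESHOLD for r in rhat.values()):
        logger.warning("pv_fit: convergence flagged, max rhat=%.3f", max(rhat.values()))
    posterior = PosteriorDraws(
        draws=draws, n_chains=mcmc.n_chains, rhat=rhat, seed=seed, chain_index=chain_idx
    )
    fit = BayesFit("pv", posterior, sample, use_covariates, point_estimate)
    if not use_covariates:
        der = fit.derived()
        for col in der.columns:
            draws[col] = der[col].to_numpy()
    return fit


def covariate_specific_summary(
    fit: BayesFit, x: float | Sequence[float]
) -> list[FitSummary]:
    """Posterior summaries of AUC and cutoffs at requested covariate values.

    Reuses the fitted posterior (no refitting).  Values outside the convex
    hull of the observed covariates trigger an extrapolation warning.
    """
    if not fit.use_covariates:
        raise ValueError("fit was produced without covariates")
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    observed = np.concatenate([fit.sample.x0.ravel(), fit.sample.x1.ravel()])
    lo, hi = observed.min(), observed.max()
    out = []
    for xv in xs:
        if xv < lo or xv > hi:
            logger.warning(
                "covariate value %g outside observed range [%g, %g]: extrapolating",
                xv, lo, hi,
            )
        out.append(fit.summary(float(xv)))
    return out
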