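"""Semiparametric placement-value ROC model (Semi.PV).

The healthy group keeps the parametric normal regression of the PV model,
but the probit-transformed placement values of the diseased group follow a
truncated Dirichlet-process mixture of normals (stick-breaking
representation, blocked Gibbs).  In the covariate case the mixture is
shifted linearly by the covariate, sharing one slope across components.
Label switching is immaterial here because every reported quantity is a
functional of the mixture CDF, which is invariant to relabelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .bayes import (
    BayesFit,
    FitSummary,
    MCMCSettings,
    PosteriorDraws,
    PriorSpec,
    _back_transform_cutoffs,
    _check_covariates,
    _design,
    _rhat_map,
    _summ,
    _thin_chains,
    _zoom_cutoffs,
)
from .criteria import Criterion
from .data_model import BiomarkerSample

logger = logging.getLogger(__name__)

__all__ = ["MixtureState", "stick_breaking_weights", "semipv_fit", "SemiPVFit"]

_CRITERIA = [c.value for c in Criterion]
_PV_CLAMP = 1e-6


@dataclass
class MixtureState:
    """Current state of the truncated stick-breaking mixture."""

    weights: np.ndarray
    component_means: np.ndarray
    component_sds: np.ndarray
    allocations: np.ndarray
    concentration: float = 1.0

    @property
    def n_components(self) -> int:
        return self.weights.size


def stick_breaking_weights(betas: np.ndarray) -> np.ndarray:
    """Truncated stick-breaking: w_h = beta_h * prod_{l<h} (1 - beta_l).

    The last weight takes the remaining stick so the weights sum to one
    exactly.
    """
    betas = np.asarray(betas, dtype=float)
    if np.any((betas <= 0) | (betas >= 1)):
        raise ValueError("stick-breaking fractions must lie in (0, 1)")
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - betas)])
    w = np.empty(betas.size + 1)
    w[:-1] = betas * remaining[:-1]
    w[-1] = remaining[-1]
    return w


class SemiPVFit(BayesFit):
    """Semi.PV fit; derived metrics use the mixture CDF as the PV law."""

    def __init__(self, posterior, sample, use_covariates, point_estimate,
                 mix_means, mix_sds, mix_weights):
        super().__init__("semipv", posterior, sample, use_covariates, point_estimate)
        self.mix_means = mix_means      # (draws, H)
        self.mix_sds = mix_sds          # (draws, H)
        self.mix_weights = mix_weights  # (draws, H)

    def derived(self, x: float | None = None) -> pd.DataFrame:
        d = self.posterior.draws
        if self.use_covariates:
            if x is None:
                raise ValueError("covariate fit: specify the covariate value x")
            mu0 = d["beta00"].to_numpy() + d["beta10"].to_numpy() * x
            shift = d["beta1"].to_numpy() * x
        else:
            mu0 = d["beta00"].to_numpy()
            shift = np.zeros(len(d))
        s0 = d["sigma0"].to_numpy()
        means = self.mix_means + shift[:, None]
        sds = self.mix_sds
        wts = self.mix_weights

        def F(q):  # mixture CDF of the probit placement value, (draws, grid)
            return np.sum(
                wts[:, None, :]
                * ndtr((q[..., None] - means[:, None, :]) / sds[:, None, :]),
                axis=-1,
            )

        # AUC: ROC(t) = F(probit(t)) is linear in the mixture components, so
        # the integral decomposes exactly into weighted binormal AUCs
        auc = np.sum(wts * ndtr(-means / np.sqrt(1.0 + sds**2)), axis=1)

        lo_w = np.min(means - 5 * sds, axis=1)
        hi_w = np.max(means + 5 * sds, axis=1)
        # cutoff c maps to probit PV -(c - mu0)/s0; search range from both
        lo = np.minimum(mu0 - 5 * s0, mu0 - hi_w * s0)
        hi = np.maximum(mu0 + 5 * s0, mu0 - lo_w * s0)
        se_of = lambda c: F(-(c - mu0[:, None]) / s0[:, None])
        sp_of = lambda c: ndtr((c - mu0[:, None]) / s0[:, None])
        cuts = _zoom_cutoffs(se_of, sp_of, lo, hi, auc)
        out = pd.DataFrame({"auc": auc})
        for k in _CRITERIA:
            out[f"c{k}"] = cuts[k]
        return _back_transform_cutoffs(out, self.sample)


def semipv_fit(
    sample: BiomarkerSample,
    use_covariates: bool = False,
    priors: PriorSpec = PriorSpec(),
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    n_components: int = 20,
    concentration: float = 1.0,
    point_estimate: str = "mean",
) -> SemiPVFit:
    """Fit the semiparametric placement-value model by blocked Gibbs.

    Base measure on mixture atoms matches the parametric priors
    (means N(0, 100), variances IG(0.01, 0.01)); the truncation level
    defaults to 20 components with concentration 1.  Samples of fewer than
    30 subjects per group trigger a warning: the mixture is weakly
    identified there.
    """
    _check_covariates(sample, use_covariates)
    if min(sample.n0, sample.n1) < 30:
        logger.warning("semipv_fit: fewer than 30 subjects per group; "
                       "mixture estimates may be unstable")
    mcmc = mcmc or MCMCSettings()
    H = n_components
    y0, y1 = sample.y0, sample.y1
    X0 = _design(sample.x0, sample.n0, use_covariates)
    X1z = _design(sample.x1, sample.n1, use_covariates)
    p0 = X0.shape[1]
    x1 = (
        sample.x1[:, 0] if (use_covariates and sample.x1 is not None)
        else np.zeros(sample.n1)
    )
    names = ["beta00", "beta10"][:p0] + ["sigma0"] + (
        ["beta1"] if use_covariates else []
    )

    gamma_ols, *_ = np.linalg.lstsq(X0, y0, rcond=None)
    resid0 = y0 - X0 @ gamma_ols
    sigma0_init = float(np.sqrt(max(resid0 @ resid0 / max(y0.size - p0, 1), 1e-8)))

    def probit_pv(gamma, log_s0):
        z = 1.0 - ndtr((y1 - X1z @ gamma) / np.exp(log_s0))
        z = np.clip(z, _PV_CLAMP, 1.0 - _PV_CLAMP)
        return ndtri(z)

    def healthy_base(gamma, log_s0):
        """Healthy-likelihood terms plus the y1 -> w change of variables."""
        s0 = np.exp(log_s0)
        r0 = y0 - X0 @ gamma
        lp = -y0.size * log_s0 - 0.5 * float(r0 @ r0) / s0**2
        std1 = (y1 - X1z @ gamma) / s0
        w = ndtri(np.clip(1.0 - ndtr(std1), _PV_CLAMP, 1.0 - _PV_CLAMP))
        lp += float(np.sum(-0.5 * std1**2 + 0.5 * w**2)) - y1.size * log_s0
        lp += -0.5 * float(gamma @ gamma) / priors.coef_variance
        lp += -2.0 * priors.var_shape * log_s0 - priors.var_rate / s0**2 + 2.0 * log_s0
        return lp, w

    def mixture_term(w, wts, means, sds, beta1):
        comp = wts * np.exp(
            -0.5 * ((w[:, None] - means - beta1 * x1[:, None]) / sds) ** 2
        ) / sds
        dens = np.maximum(comp.sum(axis=1), 1e-300)
        return float(np.sum(np.log(dens)))

    ss = np.random.SeedSequence(seed)
    chain_arrays = []
    mix_store = {"means": [], "sds": [], "weights": []}
    for chain_seed in ss.spawn(mcmc.n_chains):
        rng = np.random.default_rng(chain_seed)
        gamma = gamma_ols.copy()
        log_s0 = float(np.log(sigma0_init))
        beta1 = 0.0
        w = probit_pv(gamma, log_s0)
        means = np.quantile(w, np.linspace(0.05, 0.95, H))
        sds = np.full(H, max(np.std(w), 0.3))
        wts = np.full(H, 1.0 / H)
        alloc = rng.integers(0, H, y1.size)
        scale = 0.1 * np.ones(p0 + 1)
        accepted = proposed = 0
        base, w = healthy_base(gamma, log_s0)
        n_keep = mcmc.n_iter - mcmc.n_burn
        out = np.empty((n_keep, len(names)))
        mix_out = {
            "means": np.empty((n_keep, H)),
            "sds": np.empty((n_keep, H)),
            "weights": np.empty((n_keep, H)),
        }
        for it in range(mcmc.n_iter):
            # --- allocations ---
            resid = w[:, None] - means - beta1 * x1[:, None]
            logp = np.log(np.maximum(wts, 1e-300)) - np.log(sds) - 0.5 * (resid / sds) ** 2
            logp -= logp.max(axis=1, keepdims=True)
            prob = np.exp(logp)
            prob /= prob.sum(axis=1, keepdims=True)
            u = rng.uniform(size=y1.size)[:, None]
            alloc = (prob.cumsum(axis=1) < u).sum(axis=1)
            # --- component parameters (conjugate given allocations) ---
            wc = w - beta1 * x1
            counts = np.bincount(alloc, minlength=H)
            sums = np.bincount(alloc, weights=wc, minlength=H)
            var_h = sds**2
            post_var = 1.0 / (counts / var_h + 1.0 / priors.coef_variance)
            means = post_var * (sums / var_h) + np.sqrt(post_var) * rng.standard_normal(H)
            sq = np.bincount(alloc, weights=(wc - means[alloc]) ** 2, minlength=H)
            shape = priors.var_shape + 0.5 * counts
            rate = priors.var_rate + 0.5 * sq
            # numerical guard: empty components draw from the nearly improper
            # base measure, whose extreme tails would destabilize the CDF
            with np.errstate(divide="ignore", over="ignore"):
                sds = np.clip(np.sqrt(rate / rng.gamma(shape)), 1e-2, 1e2)
            # --- stick-breaking weights ---
            tail = counts[::-1].cumsum()[::-1]
            a = 1.0 + counts[:-1]
            b = concentration + tail[1:]
            betas = np.clip(rng.beta(a, b), 1e-12, 1.0 - 1e-12)
            wts = stick_breaking_weights(betas)
            # --- covariate slope (conjugate given allocations) ---
            if use_covariates:
                prec_b = np.sum(x1**2 / sds[alloc] ** 2) + 1.0 / priors.coef_variance
                mean_b = np.sum(x1 * (w - means[alloc]) / sds[alloc] ** 2) / prec_b
                beta1 = mean_b + rng.standard_normal() / np.sqrt(prec_b)
            # --- healthy parameters by Metropolis ---
            step = rng.standard_normal(p0 + 1) * scale
            gamma_prop = gamma + step[:p0]
            log_s0_prop = log_s0 + step[p0]
            base_prop, w_prop = healthy_base(gamma_prop, log_s0_prop)
            lp_cur = base + mixture_term(w, wts, means, sds, beta1)
            lp_prop = base_prop + mixture_term(w_prop, wts, means, sds, beta1)
            proposed += 1
            if np.log(rng.uniform()) < lp_prop - lp_cur:
                gamma, log_s0, base, w = gamma_prop, log_s0_prop, base_prop, w_prop
                accepted += 1
            if it < mcmc.n_burn and proposed % 100 == 0:
                rate_acc = accepted / proposed
                if rate_acc < 0.20:
                    scale *= 0.8
                elif rate_acc > 0.40:
                    scale *= 1.25
                accepted = proposed = 0
            if it >= mcmc.n_burn:
                row = it - mcmc.n_burn
                out[row, :p0] = gamma
                out[row, p0] = np.exp(log_s0)
                if use_covariates:
                    out[row, p0 + 1] = beta1
                mix_out["means"][row] = means
                mix_out["sds"][row] = sds
                mix_out["weights"][row] = wts
        chain_arrays.append(out)
        for k in mix_store:
            mix_store[k].append(mix_out[k])

    rhat = _rhat_map(chain_arrays, names)
    kept, chain_idx = _thin_chains(chain_arrays, mcmc.n_retained)
    kept_mix = {}
    for k in mix_store:
        arr, _ = _thin_chains(mix_store[k], mcmc.n_retained)
        kept_mix[k] = arr
    draws = pd.DataFrame(kept, columns=names)
    if not use_covariates:
        draws["beta1"] = 0.0
    posterior = PosteriorDraws(
        draws=draws, n_chains=mcmc.n_chains, rhat=rhat, seed=seed, chain_index=chain_idx
    )
    fit = SemiPVFit(
        posterior, sample, use_covariates, point_estimate,
        kept_mix["means"], kept_mix["sds"], kept_mix["weights"],
    )
    if not use_covariates:
        der = fit.derived()
        for col in der.columns:
            draws[col] = der[col].to_numpy()
    return fit
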