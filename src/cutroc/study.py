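"""Replicate-level simulation driver and bias summarization.

:func:`run_study` reproduces the design of the bias study: for each
(scenario, model) cell it generates replicates, fits the model, subtracts
the oracle truth from each point estimate (posterior mean for the Bayesian
models, direct estimate otherwise) and reports the median and IQR of the
biases.  Per-replicate seeds are ``seed + replicate index``, so results do
not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import bayes, empirical, semipv
from .criteria import Criterion
from .data_model import BiomarkerSample
from .scenarios import generate, get_scenario, truth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "summarize_bias", "fit_models", "MODEL_NAMES"]

MODEL_NAMES = ("emp", "nonpar", "bn", "pv", "semipv")
_METRICS = ["AUC"] + [c.value for c in Criterion]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one bias study run.

    Defaults follow the bias-study design standard in this literature:
    1000 replicates, N = 100 per group, covariate metrics evaluated at
    x = 0 and x = 1.  ``full_mcmc`` restores the two-chain/10k-iteration sampler inside the
    simulation; by default a cheaper single-chain sampler is used (bias
    medians are insensitive to chain length, runtime is not).
    """

    scenarios: tuple[str, ...]
    models: tuple[str, ...]
    n_replicates: int = 1000
    n_per_group: int = 100
    seed: int = 0
    covariate_values: tuple[float, ...] = (0.0, 1.0)
    full_mcmc: bool = False
    mixture_literal: bool = True
    bias_sign: str = "estimate_minus_truth"
    semipv_components: int = 20

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.n_per_group not in (50, 100, 500) and self.n_per_group < 4:
            raise ValueError("n_per_group too small")


def summarize_bias(biases: Sequence[float]) -> tuple[float, float]:
    """Median and IQR (linear-interpolation / type-7 quantiles)."""
    arr = np.asarray(list(biases), dtype=float)
    if arr.size == 0:
        raise ValueError("no biases to summarize")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1)


def _point_estimates(
    model: str,
    sample: BiomarkerSample,
    seed: int,
    config: RunConfig,
    xs: tuple[float, ...] | None,
) -> dict[float | None, dict[str, float]]:
    """Point estimates of AUC and the four cutoffs, keyed by covariate value."""
    if model == "emp":
        roc = empirical.empirical_fit(sample)
        cuts = empirical.empirical_cutoffs(sample)
        return {None: {"AUC": roc.auc, **{k: cuts[k].cutoff for k in cuts}}}
    if model == "nonpar":
        roc, cuts = empirical.nonpar_fit(sample)
        return {None: {"AUC": roc.auc, **{k: cuts[k].cutoff for k in cuts}}}
    mcmc = bayes.MCMCSettings() if config.full_mcmc else bayes.MCMCSettings.reduced()
    use_cov = xs is not None
    if model == "bn":
        fit = bayes.bn_fit(sample, use_covariates=use_cov, mcmc=mcmc, seed=seed)
    elif model == "pv":
        fit = bayes.pv_fit(sample, use_covariates=use_cov, mcmc=mcmc, seed=seed)
    elif model == "semipv":
        fit = semipv.semipv_fit(
            sample, use_covariates=use_cov, mcmc=mcmc, seed=seed,
            n_components=config.semipv_components,
        )
    else:  # pragma: no cover
        raise ValueError(model)
    out: dict[float | None, dict[str, float]] = {}
    for x in xs if use_cov else (None,):
        s = fit.summary(x)
        out[x] = {"AUC": s.auc[0], **{k: s.cutoffs[k][0] for k in s.cutoffs}}
    return out


def fit_models(
    sample: BiomarkerSample,
    models: Sequence[str],
    seed: int = 0,
    config: RunConfig | None = None,
    xs: tuple[float, ...] | None = None,
) -> dict[str, dict[float | None, dict[str, float]]]:
    """Fit several models to one sample; see :func:`_point_estimates`."""
    config = config or RunConfig(scenarios=(), models=tuple(models))
    return {
        m: _point_estimates(m, sample, seed, config, xs) for m in models
    }


def run_study(config: RunConfig) -> pd.DataFrame:
    """Run the bias study and return the bias table.

    Columns: mechanism, auc_level, model, x, metric, median_bias, iqr_bias,
    n_reps, n_failures.  A cell where every replicate failed is reported
    with NaN summaries and the failure count.
    """
    rows = []
    for name in config.scenarios:
        scenario = get_scenario(
            name, config.n_per_group, config.mixture_literal
        )
        xs = config.covariate_values if scenario.has_covariates else None
        truths = {
            x: truth(scenario, x) for x in (xs if xs else (None,))
        }
        for model in config.models:
            if scenario.has_covariates and model in ("emp", "nonpar"):
                raise ValueError(
                    f"model {model!r} cannot accommodate covariates "
                    f"(scenario {name!r})"
                )
            biases: dict[tuple[float | None, str], list[float]] = {
                (x, met): [] for x in truths for met in _METRICS
            }
            n_failures = 0
            for r in range(config.n_replicates):
                rep_seed = config.seed + r
                sample = generate(scenario, seed=rep_seed)
                try:
                    est = _point_estimates(model, sample, rep_seed, config, xs)
                except Exception as exc:  # noqa: BLE001
                    n_failures += 1
                    logger.warning("replicate %d failed for %s/%s: %s",
                                   r, name, model, exc)
                    continue
                for x, vals in est.items():
                    tr = truths[x]
                    ref = {"AUC": tr.true_auc, **tr.cutoffs}
                    for met in _METRICS:
                        b = vals[met] - ref[met]
                        if config.bias_sign == "truth_minus_estimate":
                            b = -b
                        biases[(x, met)].append(b)
            for (x, met), vals in biases.items():
                if vals:
                    med, iqr = summarize_bias(vals)
                else:
                    med = iqr = float("nan")
                rows.append({
                    "mechanism": scenario.mechanism,
                    "auc_level": scenario.auc_level,
                    "model": model,
                    "x": x,
                    "metric": met,
                    "median_bias": med,
                    "iqr_bias": iqr,
                    "n_reps": len(vals),
                    "n_failures": n_failures,
                })
    return pd.DataFrame(rows)
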