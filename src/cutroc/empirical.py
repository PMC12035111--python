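"""Covariate-free nonparametric ROC estimators.

Two estimators live here: the plain empirical (Emp) model, whose ROC curve
is a step function of the two empirical CDFs, and a Gaussian-kernel
smoothed model (NonPar) with Silverman's rule-of-thumb bandwidth per group.
Neither accommodates covariates; confidence intervals come from a
stratified percentile bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata

from .criteria import (
    Criterion,
    SearchGrid,
    auc_from_roc,
    criterion_value,
    optimal_cutoff,
    _pick_candidate,
)
from .data_model import (
    BiomarkerSample,
    CutoffResult,
    DistributionEstimate,
    ROCCurveEstimate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EmpiricalCDF",
    "KernelCDF",
    "BootstrapSummary",
    "empirical_auc",
    "empirical_fit",
    "empirical_cutoffs",
    "silverman_bandwidth",
    "nonpar_fit",
    "bootstrap_interval",
    "bootstrap_intervals",
    "bootstrap_table",
]


class UnsupportedModelError(ValueError):
    """Raised when a model cannot accommodate the requested analysis."""


def _require_no_covariates(sample: BiomarkerSample, model: str) -> None:
    if sample.has_covariates:
        raise UnsupportedModelError(
            f"the {model} model cannot accommodate covariates; "
            "use the BN, PV or Semi.PV models instead"
        )


class EmpiricalCDF(DistributionEstimate):
    """Right-continuous empirical CDF with generalized-inverse quantile."""

    def __init__(self, values: np.ndarray):
        sorted_values = np.sort(np.asarray(values, dtype=float))
        n = sorted_values.size

        def cdf(c):
            return np.searchsorted(sorted_values, np.asarray(c), side="right") / n

        def quantile(p):
            p = np.asarray(p, dtype=float)
            idx = np.clip(np.ceil(p * n).astype(int) - 1, 0, n - 1)
            return sorted_values[idx]

        super().__init__(
            cdf=cdf,
            quantile=quantile,
            support_hint=(float(sorted_values[0]) - 1.0, float(sorted_values[-1]) + 1.0),
        )
        object.__setattr__(self, "sorted_values", sorted_values)
        object.__setattr__(self, "n", n)


class KernelCDF(DistributionEstimate):
    """Gaussian-kernel smoothed CDF: mean of Phi((c - y_i)/h).

    Strictly increasing, so the quantile is well defined; it is computed by
    monotone interpolation on a dense grid followed by Newton polishing
    against the exact kernel CDF/PDF.
    """

    def __init__(self, values: np.ndarray, bandwidth: float):
        values = np.asarray(values, dtype=float)
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        lo = float(values.min() - 8 * bandwidth)
        hi = float(values.max() + 8 * bandwidth)

        def cdf(c):
            c = np.asarray(c, dtype=float)
            out = ndtr((c[..., None] - values) / bandwidth).mean(axis=-1)
            return out if out.ndim else float(out)

        def pdf(c):
            c = np.asarray(c, dtype=float)
            z = (c[..., None] - values) / bandwidth
            out = np.exp(-0.5 * z * z).mean(axis=-1) / (
                bandwidth * np.sqrt(2.0 * np.pi)
            )
            return out

        def quantile(p):
            p = np.asarray(p, dtype=float)
            pp = np.clip(p, 1e-10, 1.0 - 1e-10)
            a = np.full(pp.shape, lo)
            b = np.full(pp.shape, hi)
            for _ in range(40):  # vectorized bisection: bracket to ~1e-12*range
                mid = 0.5 * (a + b)
                left = np.asarray(cdf(mid), dtype=float) < pp
                a = np.where(left, mid, a)
                b = np.where(left, b, mid)
            c = 0.5 * (a + b)
            for _ in range(2):  # Newton polish where the density is healthy
                dens = pdf(c)
                step = np.where(
                    dens > 1e-12, (np.asarray(cdf(c), dtype=float) - pp), 0.0
                ) / np.maximum(dens, 1e-12)
                c = np.clip(c - step, lo, hi)
            return c if c.ndim else float(c)

        super().__init__(cdf=cdf, quantile=quantile, support_hint=(lo, hi))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "bandwidth", float(bandwidth))


@dataclass(frozen=True)
class BootstrapSummary:
    """Percentile bootstrap interval around a point estimate."""

    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int


def empirical_auc(y0: np.ndarray, y1: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted one half.

    Equals the trapezoid area under the empirical ROC curve exactly.
    """
    y0 = np.asarray(y0, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    if y0.size == 0 or y1.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([y0, y1]))
    r1 = ranks[y0.size :].sum()
    return float((r1 - y1.size * (y1.size + 1) / 2.0) / (y0.size * y1.size))


def _empirical_candidates(y0: np.ndarray, y1: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive pooled order statistics, padded by one
    candidate below the minimum and one above the maximum.

    Criterion surfaces of the empirical model are constant between
    observations, so this finite set contains a global optimum.
    """
    pooled = np.unique(np.concatenate([y0, y1]))
    mids = 0.5 * (pooled[:-1] + pooled[1:])
    return np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])


def empirical_fit(sample: BiomarkerSample) -> ROCCurveEstimate:
    """Empirical ROC curve and Mann-Whitney AUC."""
    _require_no_covariates(sample, "empirical (Emp)")
    f0 = EmpiricalCDF(sample.y0)
    f1 = EmpiricalCDF(sample.y1)

    def roc(t):
        t = np.asarray(t, dtype=float)
        tt = np.clip(t, 1e-12, 1.0)
        inner = 1.0 - np.asarray(f1.cdf(f0.quantile(1.0 - tt)), dtype=float)
        out = np.where(t <= 0.0, 0.0, np.where(t >= 1.0, 1.0, inner))
        return out if out.ndim else float(out)

    return ROCCurveEstimate(
        roc=roc, auc=empirical_auc(sample.y0, sample.y1), source_model="Emp"
    )


def empirical_cutoffs(
    sample: BiomarkerSample, iu_secondary: bool = True
) -> dict[str, CutoffResult]:
    """All four optimal cutoffs by exhaustive scan over the candidate set."""
    _require_no_covariates(sample, "empirical (Emp)")
    y0s = np.sort(sample.y0)
    y1s = np.sort(sample.y1)
    cand = _empirical_candidates(sample.y0, sample.y1)
    sp = np.searchsorted(y0s, cand, side="right") / y0s.size
    se = 1.0 - np.searchsorted(y1s, cand, side="right") / y1s.size
    auc = empirical_auc(sample.y0, sample.y1)
    out: dict[str, CutoffResult] = {}
    for criterion in Criterion:
        value = np.asarray(criterion_value(criterion, se, sp, auc), dtype=float)
        loss = -value if criterion.maximize else value
        idx, degenerate = _pick_candidate(
            loss, se, sp, iu_secondary and criterion is Criterion.IU
        )
        out[criterion.value] = CutoffResult(
            criterion=criterion.value,
            cutoff=float(sample.to_original_scale(cand[idx])),
            sensitivity=float(se[idx]),
            specificity=float(sp[idx]),
            criterion_value=float(value[idx]),
            degenerate_flag=degenerate,
        )
    return out


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(values, ddof=1))
    iqr = float(np.percentile(values, 75) - np.percentile(values, 25))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("values have zero spread; bandwidth undefined")
    return 0.9 * spread * values.size ** (-0.2)


def nonpar_fit(
    sample: BiomarkerSample,
    bandwidth0: float | None = None,
    bandwidth1: float | None = None,
    iu_secondary: bool = True,
) -> tuple[ROCCurveEstimate, dict[str, CutoffResult]]:
    """Kernel-smoothed (NonPar) ROC fit with the four optimal cutoffs."""
    _require_no_covariates(sample, "kernel nonparametric (NonPar)")
    h0 = silverman_bandwidth(sample.y0) if bandwidth0 is None else bandwidth0
    h1 = silverman_bandwidth(sample.y1) if bandwidth1 is None else bandwidth1
    f0 = KernelCDF(sample.y0, h0)
    f1 = KernelCDF(sample.y1, h1)

    def roc(t):
        t = np.asarray(t, dtype=float)
        return 1.0 - np.asarray(f1.cdf(f0.quantile(1.0 - t)), dtype=float)

    auc = auc_from_roc(roc)
    grid = SearchGrid.from_distributions(f0, f1)
    cutoffs: dict[str, CutoffResult] = {}
    for criterion in Criterion:
        res = optimal_cutoff(
            criterion, f0, f1, auc=auc, grid=grid, iu_secondary=iu_secondary
        )
        cutoffs[criterion.value] = CutoffResult(
            criterion=res.criterion,
            cutoff=float(sample.to_original_scale(res.cutoff)),
            sensitivity=res.sensitivity,
            specificity=res.specificity,
            criterion_value=res.criterion_value,
            degenerate_flag=res.degenerate_flag,
        )
    roc_est = ROCCurveEstimate(roc=roc, auc=auc, source_model="NonPar")
    return roc_est, cutoffs


def bootstrap_table(
    statistic: Callable[[BiomarkerSample], dict[str, float]],
    sample: BiomarkerSample,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapSummary]:
    """Stratified percentile bootstrap (2.5/97.5) of a dict-valued statistic.

    Resampling is within group (preserving the two group sizes), so one
    expensive model fit per replicate serves every reported metric.
    Replicates on which the statistic fails are dropped with a logged
    count; more than 10% failures aborts.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    points = {k: float(v) for k, v in statistic(sample).items()}
    reps: dict[str, list[float]] = {k: [] for k in points}
    failures = 0
    for _ in range(n_boot):
        idx0 = rng.integers(0, sample.n0, sample.n0)
        idx1 = rng.integers(0, sample.n1, sample.n1)
        boot = BiomarkerSample(
            sample.y0[idx0], sample.y1[idx1], direction=sample.direction
        )
        try:
            vals = statistic(boot)
        except Exception:  # noqa: BLE001 - replicate-level robustness
            failures += 1
            continue
        for k in reps:
            reps[k].append(float(vals[k]))
    if failures:
        logger.info("bootstrap_table: %d/%d replicates failed", failures, n_boot)
    if failures > 0.1 * n_boot:
        raise RuntimeError(f"bootstrap failed on {failures}/{n_boot} replicates")
    out = {}
    for k, vals in reps.items():
        lower, upper = np.percentile(vals, [2.5, 97.5])
        out[k] = BootstrapSummary(
            point=points[k], lower=float(lower), upper=float(upper),
            n_boot=n_boot, seed=seed,
        )
    return out


def bootstrap_intervals(
    statistics: dict[str, Callable[[BiomarkerSample], float]],
    sample: BiomarkerSample,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapSummary]:
    """Bootstrap several scalar statistics on one shared resample stream."""

    def combined(s: BiomarkerSample) -> dict[str, float]:
        return {k: float(fn(s)) for k, fn in statistics.items()}

    return bootstrap_table(combined, sample, n_boot, seed)


def bootstrap_interval(
    statistic: Callable[[BiomarkerSample], float],
    sample: BiomarkerSample,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapSummary:
    """Stratified percentile bootstrap (2.5/97.5) of one scalar statistic."""
    return bootstrap_intervals({"stat": statistic}, sample, n_boot, seed)["stat"]
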