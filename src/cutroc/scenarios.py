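"""Simulation data generators with an analytic truth oracle.

Every mechanism of the bias study lives in a YAML registry shipped with
the package; :func:`generate` draws per-subject data from the literal
generating law and :func:`truth` recomputes the true AUC (closed form
where available, numeric integration otherwise) and the true optimal
cutoffs by a dense-grid scan of each criterion on the analytic CDFs,
refined by golden-section.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import yaml
from scipy import stats
from scipy.integrate import quad
from scipy.special import ndtr

from .criteria import Criterion, _golden_section, criterion_value
from .data_model import BiomarkerSample, DistributionEstimate

__all__ = ["ScenarioSpec", "TruthRecord", "registry", "get_scenario", "generate", "truth"]

COVARIATE_LOW, COVARIATE_HIGH = -0.5, 1.5


@dataclass(frozen=True)
class ScenarioSpec:
    """A named data-generating mechanism with its true parameters."""

    mechanism: str
    auc_level: str
    parameters: dict[str, float]
    n_per_group: int = 100
    mixture_literal: bool = True

    @property
    def name(self) -> str:
        if self.auc_level == "not_applicable":
            return self.mechanism
        return f"{self.mechanism}:{self.auc_level}"

    @property
    def has_covariates(self) -> bool:
        return self.mechanism.startswith("Cov_")


@dataclass(frozen=True)
class TruthRecord:
    """Oracle values for one scenario (optionally at a covariate value)."""

    true_auc: float
    cutoffs: dict[str, float]
    evaluated_at_x: float | None = None


@lru_cache(maxsize=1)
def registry() -> dict[str, dict[str, dict[str, float]]]:
    text = (
        importlib.resources.files("cutroc").joinpath("scenarios.yaml").read_text()
    )
    return yaml.safe_load(text)


def get_scenario(
    name: str, n_per_group: int = 100, mixture_literal: bool = True
) -> ScenarioSpec:
    """Look up ``"Mechanism:level"`` (or a bare covariate mechanism name)."""
    mechanism, _, level = name.partition(":")
    level = level or "not_applicable"
    reg = registry()
    if mechanism not in reg or level not in reg[mechanism]:
        raise KeyError(f"unknown scenario {name!r}")
    return ScenarioSpec(
        mechanism=mechanism,
        auc_level=level,
        parameters=dict(reg[mechanism][level]),
        n_per_group=n_per_group,
        mixture_literal=mixture_literal,
    )


def _combined_normal(pi: float, mu_a: float, sd_a: float, mu_b: float, sd_b: float):
    """Single normal carrying the combined mean/variance of the two components."""
    mean = pi * mu_a + (1 - pi) * mu_b
    sd = float(np.sqrt(pi**2 * sd_a**2 + (1 - pi) ** 2 * sd_b**2))
    return mean, sd


def _draw_mixture(rng, n, pi, mu_a, sd_a, mu_b, sd_b):
    pick = rng.uniform(size=n) < pi
    return np.where(
        pick, rng.normal(mu_a, sd_a, n), rng.normal(mu_b, sd_b, n)
    )


def generate(scenario: ScenarioSpec, seed: int = 0) -> BiomarkerSample:
    """Draw one replicate from the scenario's literal generating law."""
    rng = np.random.default_rng(seed)
    p = scenario.parameters
    n = scenario.n_per_group
    m = scenario.mechanism
    if m in ("BN_equal", "BN_unequal"):
        y0 = rng.normal(p["mu0"], p["sigma0"], n)
        y1 = rng.normal(p["mu1"], p["sigma1"], n)
    elif m == "Skewed_I":
        y0 = rng.normal(p["mu0"], p["sigma0"], n) ** 2
        y1 = rng.normal(p["mu1"], p["sigma1"], n) ** 2
    elif m == "Skewed_II":
        y0 = rng.lognormal(p["mu0"], p["sigma0"], n)
        y1 = rng.lognormal(p["mu1"], p["sigma1"], n)
    elif m == "Skewed_III":
        y0 = rng.gamma(p["k"], p["theta0"], n)
        y1 = rng.gamma(p["k"], p["theta1"], n)
    elif m == "Mixed_I":
        y0 = rng.normal(p["mu0"], p["sigma0"], n)
        if scenario.mixture_literal:
            mu, sd = _combined_normal(
                p["pi1"], p["mu11"], p["sigma11"], p["mu12"], p["sigma12"]
            )
            y1 = rng.normal(mu, sd, n)
        else:
            y1 = _draw_mixture(
                rng, n, p["pi1"], p["mu11"], p["sigma11"], p["mu12"], p["sigma12"]
            )
    elif m == "Mixed_II":
        if scenario.mixture_literal:
            mu0, sd0 = _combined_normal(
                p["pi0"], p["mu01"], p["sigma01"], p["mu02"], p["sigma02"]
            )
            mu1, sd1 = _combined_normal(
                p["pi1"], p["mu11"], p["sigma11"], p["mu12"], p["sigma12"]
            )
            y0 = rng.normal(mu0, sd0, n)
            y1 = rng.normal(mu1, sd1, n)
        else:
            y0 = _draw_mixture(
                rng, n, p["pi0"], p["mu01"], p["sigma01"], p["mu02"], p["sigma02"]
            )
            y1 = _draw_mixture(
                rng, n, p["pi1"], p["mu11"], p["sigma11"], p["mu12"], p["sigma12"]
            )
    elif m in ("Cov_BN", "Cov_Skewed", "Cov_Mixed"):
        x0 = rng.uniform(COVARIATE_LOW, COVARIATE_HIGH, n)
        x1 = rng.uniform(COVARIATE_LOW, COVARIATE_HIGH, n)
        if m == "Cov_BN":
            y0 = rng.normal(p["b00"] + p["b01"] * x0, p["sigma0"])
            y1 = rng.normal(p["b10"] + p["b11"] * x1, p["sigma1"])
        elif m == "Cov_Skewed":
            y0 = rng.gamma(p["k"], p["b00"] + p["b01"] * x0)
            y1 = rng.gamma(p["k"], p["b10"] + p["b11"] * x1)
        else:  # Cov_Mixed
            y0 = rng.normal(p["a00"] + p["a01"] * x0, p["sigma0"])
            mu11 = p["a101"] + p["a111"] * x1
            mu12 = p["a102"] + p["a112"] * x1
            mu1 = p["pi1"] * mu11 + (1 - p["pi1"]) * mu12
            y1 = rng.normal(mu1, p["sigma1"])
        return BiomarkerSample(
            y0=y0, y1=y1, x0=x0[:, None], x1=x1[:, None], covariate_names=("x",)
        )
    else:
        raise ValueError(f"unknown mechanism {m!r}")
    return BiomarkerSample(y0=y0, y1=y1)


class _SquaredNormalCDF:
    """Law of W^2 for W ~ N(mu, sigma^2): the square-root-scale normal."""

    def __init__(self, mu: float, sigma: float):
        self.mu, self.sigma = mu, sigma

    def cdf(self, y):
        y = np.asarray(y, dtype=float)
        s = np.sqrt(np.maximum(y, 0.0))
        out = ndtr((s - self.mu) / self.sigma) - ndtr((-s - self.mu) / self.sigma)
        return np.where(y <= 0, 0.0, out)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        from scipy.optimize import brentq

        hi = (abs(self.mu) + 10 * self.sigma) ** 2

        def one(p):
            return brentq(lambda y: float(self.cdf(y)) - p, 0.0, hi, xtol=1e-12)

        if q.ndim == 0:
            return one(float(q))
        return np.array([one(v) for v in q.ravel()]).reshape(q.shape)


def _analytic_laws(scenario: ScenarioSpec, x: float | None = None):
    """Frozen scipy-like laws (cdf/ppf) of the two groups, given x if needed."""
    p = scenario.parameters
    m = scenario.mechanism
    if m in ("BN_equal", "BN_unequal"):
        return stats.norm(p["mu0"], p["sigma0"]), stats.norm(p["mu1"], p["sigma1"])
    if m == "Skewed_I":
        return (
            _SquaredNormalCDF(p["mu0"], p["sigma0"]),
            _SquaredNormalCDF(p["mu1"], p["sigma1"]),
        )
    if m == "Skewed_II":
        return (
            stats.lognorm(s=p["sigma0"], scale=np.exp(p["mu0"])),
            stats.lognorm(s=p["sigma1"], scale=np.exp(p["mu1"])),
        )
    if m == "Skewed_III":
        return (
            stats.gamma(p["k"], scale=p["theta0"]),
            stats.gamma(p["k"], scale=p["theta1"]),
        )
    if m == "Mixed_I":
        mu1, sd1 = _combined_normal(
            p["pi1"], p["mu11"], p["sigma11"], p["mu12"], p["sigma12"]
        )
        return stats.norm(p["mu0"], p["sigma0"]), stats.norm(mu1, sd1)
    if m == "Mixed_II":
        mu0, sd0 = _combined_normal(
            p["pi0"], p["mu01"], p["sigma01"], p["mu02"], p["sigma02"]
        )
        mu1, sd1 = _combined_normal(
            p["pi1"], p["mu11"], p["sigma11"], p["mu12"], p["sigma12"]
        )
        return stats.norm(mu0, sd0), stats.norm(mu1, sd1)
    if x is None:
        raise ValueError(f"scenario {m} requires a covariate value x")
    if m == "Cov_BN":
        return (
            stats.norm(p["b00"] + p["b01"] * x, p["sigma0"]),
            stats.norm(p["b10"] + p["b11"] * x, p["sigma1"]),
        )
    if m == "Cov_Skewed":
        return (
            stats.gamma(p["k"], scale=p["b00"] + p["b01"] * x),
            stats.gamma(p["k"], scale=p["b10"] + p["b11"] * x),
        )
    if m == "Cov_Mixed":
        mu11 = p["a101"] + p["a111"] * x
        mu12 = p["a102"] + p["a112"] * x
        mu1 = p["pi1"] * mu11 + (1 - p["pi1"]) * mu12
        return (
            stats.norm(p["a00"] + p["a01"] * x, p["sigma0"]),
            stats.norm(mu1, p["sigma1"]),
        )
    raise ValueError(f"unknown mechanism {m!r}")


def analytic_distributions(
    scenario: ScenarioSpec, x: float | None = None
) -> tuple[DistributionEstimate, DistributionEstimate]:
    """The generating laws wrapped in the package's distribution contract."""
    d0, d1 = _analytic_laws(scenario, x)
    return (
        DistributionEstimate(
            cdf=d0.cdf, quantile=d0.ppf,
            support_hint=(float(d0.ppf(0.001)), float(d0.ppf(0.999))),
        ),
        DistributionEstimate(
            cdf=d1.cdf, quantile=d1.ppf,
            support_hint=(float(d1.ppf(0.001)), float(d1.ppf(0.999))),
        ),
    )


def _true_auc(scenario: ScenarioSpec, d0, d1, x: float | None) -> float:
    p = scenario.parameters
    m = scenario.mechanism
    if m in ("BN_equal", "BN_unequal", "Mixed_I", "Mixed_II", "Cov_BN", "Cov_Mixed"):
        mu0, sd0 = d0.mean(), d0.std()
        mu1, sd1 = d1.mean(), d1.std()
        return float(ndtr((mu1 - mu0) / np.hypot(sd0, sd1)))
    if m == "Skewed_II":
        # AUC is invariant under the log transform: normal closed form
        return float(
            ndtr((p["mu1"] - p["mu0"]) / np.hypot(p["sigma0"], p["sigma1"]))
        )
    if m in ("Skewed_III", "Cov_Skewed"):
        # equal-shape gammas: G1/(G0+G1) ~ Beta(k, k), so
        # AUC = P(theta1*G1 > theta0*G0) = 1 - F_Beta(theta0/(theta0+theta1))
        if m == "Skewed_III":
            t0, t1 = p["theta0"], p["theta1"]
        else:
            t0, t1 = p["b00"] + p["b01"] * x, p["b10"] + p["b11"] * x
        return float(1.0 - stats.beta(p["k"], p["k"]).cdf(t0 / (t0 + t1)))
    # numeric: AUC = P(Y1 > Y0) = E_{Y0}[1 - F1(Y0)]
    if hasattr(d0, "pdf"):
        lo, hi = 0.0, float(max(d0.ppf(1 - 1e-10), d1.ppf(1 - 1e-10)))
        val, _ = quad(
            lambda y: d0.pdf(y) * (1.0 - d1.cdf(y)), lo, hi, limit=400
        )
        return float(val)
    # squared-normal case: integrate on the underlying normal scale
    mu0, s0 = p["mu0"], p["sigma0"]
    law1 = d1

    def integrand(w):
        return stats.norm.pdf(w, mu0, s0) * (1.0 - float(law1.cdf(w**2)))

    val, _ = quad(integrand, mu0 - 10 * s0, mu0 + 10 * s0, limit=400)
    return float(val)


def truth(
    scenario: ScenarioSpec,
    x: float | None = None,
    n_grid: int = 1_000_001,
    refine_tol: float = 1e-8,
) -> TruthRecord:
    """True AUC and true optimal cutoffs from the analytic distributions.

    Cutoffs come from a shared dense-grid scan of all four criteria plus a
    golden-section refinement around each grid optimum.
    """
    if scenario.has_covariates and x is None:
        raise ValueError("covariate scenario: supply the covariate value x")
    d0, d1 = _analytic_laws(scenario, x)
    auc = _true_auc(scenario, d0, d1, x)
    lo = float(min(d0.ppf(1e-4), d1.ppf(1e-4)))
    hi = float(max(d0.ppf(1 - 1e-4), d1.ppf(1 - 1e-4)))
    grid = np.linspace(lo, hi, n_grid)
    se = 1.0 - np.asarray(d1.cdf(grid), dtype=float)
    sp = np.asarray(d0.cdf(grid), dtype=float)
    cutoffs: dict[str, float] = {}
    for crit in Criterion:
        value = np.asarray(criterion_value(crit, se, sp, auc), dtype=float)
        loss = -value if crit.maximize else value
        i = int(np.argmin(loss))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, n_grid - 1)]

        def scalar(c):
            v = float(
                criterion_value(crit, 1.0 - float(d1.cdf(c)), float(d0.cdf(c)), auc)
            )
            return -v if crit.maximize else v

        cutoffs[crit.value] = float(_golden_section(scalar, a, b, refine_tol))
    return TruthRecord(true_auc=auc, cutoffs=cutoffs, evaluated_at_x=x)
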