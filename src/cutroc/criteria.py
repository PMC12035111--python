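"""Optimal-cutoff criteria as pure functionals of fitted distributions.

Four classical criteria are implemented, each a functional of the healthy
and diseased distribution functions (F0, F1):

* Youden index            J(c)  = se(c) + sp(c) - 1          (maximized)
* Closest-to-(0,1)        ER(c) = sqrt((1-se)^2 + (1-sp)^2)  (minimized)
* Concordance probability CZ(c) = se(c) * sp(c)              (maximized)
* Index of union          IU(c) = |se-AUC| + |sp-AUC|        (minimized)

The same criteria are available in the placement-value parameterization,
where the diseased distribution enters only through the CDF F of the
placement value Z = 1 - F0(Y1) and sensitivity becomes se(c) = F(1-F0(c)).

The optimizer is a deterministic dense grid scan followed by golden-section
refinement inside the best grid cell; among exact ties the smallest cutoff
wins, which makes results reproducible across platforms.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data_model import CutoffResult, DistributionEstimate

__all__ = [
    "Criterion",
    "SearchGrid",
    "PlacementValueModel",
    "criterion_value",
    "optimal_cutoff",
    "pv_optimal_cutoff",
    "auc_from_roc",
]

_TIE_TOL = 1e-9
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class Criterion(str, enum.Enum):
    J = "J"
    ER = "ER"
    CZ = "CZ"
    IU = "IU"

    @property
    def maximize(self) -> bool:
        return self in (Criterion.J, Criterion.CZ)


@dataclass(frozen=True)
class SearchGrid:
    """A bounded search range for the cutoff optimizer."""

    low: float
    high: float
    n_points: int = 2001
    refine_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"degenerate grid: low={self.low} >= high={self.high}")
        if self.n_points < 101:
            raise ValueError("n_points must be at least 101")

    @classmethod
    def from_distributions(
        cls,
        f0: DistributionEstimate,
        f1: DistributionEstimate,
        n_points: int = 2001,
        refine_tol: float = 1e-6,
    ) -> "SearchGrid":
        """Default range: pooled 0.001 and 0.999 quantiles of F0 and F1."""
        low = min(float(f0.quantile(0.001)), float(f1.quantile(0.001)))
        high = max(float(f0.quantile(0.999)), float(f1.quantile(0.999)))
        if not low < high:  # e.g. degenerate point masses
            low, high = low - 1.0, high + 1.0
        return cls(low=low, high=high, n_points=n_points, refine_tol=refine_tol)

    def candidates(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_points)


@dataclass(frozen=True)
class PlacementValueModel:
    """A fitted placement-value ROC model: healthy CDF F0 and PV CDF F."""

    f0: DistributionEstimate
    f: DistributionEstimate
    link_eta: str = "probit"


def criterion_value(
    criterion: Criterion | str,
    se: np.ndarray | float,
    sp: np.ndarray | float,
    auc: float | None = None,
) -> np.ndarray | float:
    """Evaluate one criterion at given sensitivity/specificity (vectorized)."""
    criterion = Criterion(criterion)
    se = np.asarray(se, dtype=float)
    sp = np.asarray(sp, dtype=float)
    if criterion is Criterion.J:
        out = se + sp - 1.0
    elif criterion is Criterion.ER:
        out = np.sqrt((1.0 - se) ** 2 + (1.0 - sp) ** 2)
    elif criterion is Criterion.CZ:
        out = se * sp
    elif criterion is Criterion.IU:
        if auc is None:
            raise ValueError("IU requires the model's AUC estimate")
        out = np.abs(se - auc) + np.abs(sp - auc)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown criterion {criterion}")
    return out if out.ndim else float(out)


def _golden_section(fun: Callable[[float], float], lo: float, hi: float, tol: float) -> float:
    """Deterministic golden-section minimization of ``fun`` on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


def _pick_candidate(
    loss: np.ndarray, se: np.ndarray, sp: np.ndarray, iu_secondary: bool
) -> tuple[int, bool]:
    """Index of the winning grid candidate plus a degeneracy flag.

    Ties on the primary loss are broken (for IU, optionally) by the smaller
    |se - sp|, then always by the smaller cutoff — grid order is ascending,
    so the first qualifying index is the smallest cutoff.
    """
    degenerate = bool(np.ptp(loss) <= _TIE_TOL)
    best = float(np.min(loss))
    tied = np.flatnonzero(loss <= best + _TIE_TOL)
    if iu_secondary and tied.size > 1:
        gap = np.abs(se[tied] - sp[tied])
        tied = tied[gap <= gap.min() + _TIE_TOL]
    return int(tied[0]), degenerate


def _optimize(
    criterion: Criterion,
    se_fun: Callable[[np.ndarray | float], np.ndarray],
    sp_fun: Callable[[np.ndarray | float], np.ndarray],
    auc: float | None,
    grid: SearchGrid,
    iu_secondary: bool,
) -> CutoffResult:
    cand = grid.candidates()
    se = np.asarray(se_fun(cand), dtype=float)
    sp = np.asarray(sp_fun(cand), dtype=float)
    value = np.asarray(criterion_value(criterion, se, sp, auc), dtype=float)
    loss = -value if criterion.maximize else value
    use_secondary = iu_secondary and criterion is Criterion.IU
    idx, degenerate = _pick_candidate(loss, se, sp, use_secondary)
    cutoff = float(cand[idx])
    if not degenerate:
        lo = float(cand[max(idx - 1, 0)])
        hi = float(cand[min(idx + 1, cand.size - 1)])

        def scalar_loss(c: float) -> float:
            v = float(
                criterion_value(criterion, float(se_fun(c)), float(sp_fun(c)), auc)
            )
            return -v if criterion.maximize else v

        refined = _golden_section(scalar_loss, lo, hi, grid.refine_tol)
        # Step-function fits can make the refined point worse; keep the better.
        if scalar_loss(refined) <= loss[idx] + _TIE_TOL:
            cutoff = min(refined, cutoff) if abs(
                scalar_loss(refined) - loss[idx]
            ) <= _TIE_TOL else refined
    se_c = float(se_fun(cutoff))
    sp_c = float(sp_fun(cutoff))
    return CutoffResult(
        criterion=criterion.value,
        cutoff=cutoff,
        sensitivity=se_c,
        specificity=sp_c,
        criterion_value=float(criterion_value(criterion, se_c, sp_c, auc)),
        degenerate_flag=degenerate,
    )


def optimal_cutoff(
    criterion: Criterion | str,
    f0: DistributionEstimate,
    f1: DistributionEstimate,
    auc: float | None = None,
    grid: SearchGrid | None = None,
    iu_secondary: bool = True,
) -> CutoffResult:
    """Optimal cutoff of one criterion under fitted (F0, F1)."""
    criterion = Criterion(criterion)
    if grid is None:
        grid = SearchGrid.from_distributions(f0, f1)
    return _optimize(
        criterion,
        se_fun=lambda c: 1.0 - np.asarray(f1.cdf(c), dtype=float),
        sp_fun=lambda c: np.asarray(f0.cdf(c), dtype=float),
        auc=auc,
        grid=grid,
        iu_secondary=iu_secondary,
    )


def pv_optimal_cutoff(
    criterion: Criterion | str,
    pv: PlacementValueModel,
    auc: float | None = None,
    grid: SearchGrid | None = None,
    iu_secondary: bool = True,
) -> CutoffResult:
    """Optimal cutoff in the placement-value parameterization.

    Sensitivity is se(c) = F(1 - F0(c)), the PV CDF evaluated at the
    survival of the healthy distribution; specificity is F0(c) as usual.
    """
    criterion = Criterion(criterion)
    if grid is None:
        lo = float(pv.f0.quantile(0.001))
        hi = float(pv.f0.quantile(0.999))
        span = hi - lo
        grid = SearchGrid(low=lo - 2 * span, high=hi + 2 * span)

    def se_fun(c):
        t = 1.0 - np.asarray(pv.f0.cdf(c), dtype=float)
        t = np.clip(t, 1e-12, 1.0 - 1e-12)
        return np.asarray(pv.f.cdf(t), dtype=float)

    return _optimize(
        criterion,
        se_fun=se_fun,
        sp_fun=lambda c: np.asarray(pv.f0.cdf(c), dtype=float),
        auc=auc,
        grid=grid,
        iu_secondary=iu_secondary,
    )


def auc_from_roc(roc: Callable[[np.ndarray], np.ndarray], n_grid: int = 2001) -> float:
    """Trapezoid integral of a ROC curve over an open grid plus its limits."""
    if n_grid < 101:
        raise ValueError("n_grid must be at least 101")
    t = np.arange(1, n_grid + 1) / (n_grid + 1.0)
    r = np.asarray(roc(t), dtype=float)
    if np.any(r < -1e-9) or np.any(r > 1.0 + 1e-9):
        raise ValueError("roc returned values outside [0, 1]")
    r = np.clip(r, 0.0, 1.0)
    t_full = np.concatenate([[0.0], t, [1.0]])
    r_full = np.concatenate([[0.0], r, [1.0]])
    return float(np.trapezoid(r_full, t_full))
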