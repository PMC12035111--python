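"""Core domain types for biomarker ROC analysis.

The working convention throughout the package is that *higher* biomarker
values indicate disease.  Samples whose biomarker runs the other way (for
instance CSF amyloid-beta, where low values flag Alzheimer's disease) are
negated internally on construction, and every reported cutoff is mapped back
to the original scale before it reaches the user.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "BiomarkerSample",
    "DistributionEstimate",
    "ROCCurveEstimate",
    "CutoffResult",
    "validate_sample",
    "sensitivity_specificity",
]


class Direction(str, enum.Enum):
    """Which tail of the biomarker distribution indicates disease."""

    higher_is_diseased = "higher"
    lower_is_diseased = "lower"


class UnusableInputError(ValueError):
    """Raised when a data set cannot support ROC estimation."""


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema."""


@dataclass(frozen=True)
class BiomarkerSample:
    """Biomarker measurements for a healthy and a diseased group.

    ``y0``/``y1`` are stored on the *internal* scale on which higher values
    indicate disease; use :meth:`to_original_scale` to map cutoffs back.
    Covariate matrices, when present, are aligned row-wise with the
    biomarker vectors and share one column order across groups.
    """

    y0: np.ndarray
    y1: np.ndarray
    x0: np.ndarray | None = None
    x1: np.ndarray | None = None
    direction: Direction = Direction.higher_is_diseased
    covariate_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        y0 = np.asarray(self.y0, dtype=float)
        y1 = np.asarray(self.y1, dtype=float)
        object.__setattr__(self, "y0", y0)
        object.__setattr__(self, "y1", y1)
        for name, arr in (("y0", y0), ("y1", y1)):
            if arr.ndim != 1:
                raise SchemaError(f"{name} must be one-dimensional")
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"{name} contains non-finite values")
            if arr.size < 2:
                raise UnusableInputError(
                    f"group {name} has {arr.size} subjects; at least 2 required"
                )
        if (self.x0 is None) != (self.x1 is None):
            raise SchemaError("covariates must be present for both groups or neither")
        if self.x0 is not None:
            x0 = np.atleast_2d(np.asarray(self.x0, dtype=float))
            x1 = np.atleast_2d(np.asarray(self.x1, dtype=float))
            if x0.shape[0] != y0.size or x1.shape[0] != y1.size:
                raise SchemaError("covariate rows must align with biomarker values")
            if x0.shape[1] != x1.shape[1]:
                raise SchemaError("covariate dimension differs between groups")
            if self.covariate_names and len(self.covariate_names) != x0.shape[1]:
                raise SchemaError("covariate_names length mismatch")
            object.__setattr__(self, "x0", x0)
            object.__setattr__(self, "x1", x1)

    @property
    def has_covariates(self) -> bool:
        return self.x0 is not None

    @property
    def n0(self) -> int:
        return self.y0.size

    @property
    def n1(self) -> int:
        return self.y1.size

    def to_original_scale(self, cutoff: float | np.ndarray) -> float | np.ndarray:
        """Map an internal-scale cutoff back to the user's biomarker scale."""
        if self.direction is Direction.lower_is_diseased:
            return -np.asarray(cutoff) if np.ndim(cutoff) else -cutoff
        return cutoff

    def without_covariates(self) -> "BiomarkerSample":
        return BiomarkerSample(self.y0, self.y1, direction=self.direction)


@dataclass(frozen=True)
class DistributionEstimate:
    """The minimal contract every fitted distribution satisfies.

    ``cdf`` must be non-decreasing, ``quantile`` its (generalized) inverse,
    and ``support_hint`` brackets the region where the CDF moves from
    essentially 0 to essentially 1.
    """

    cdf: Callable[[np.ndarray | float], np.ndarray | float]
    quantile: Callable[[np.ndarray | float], np.ndarray | float]
    support_hint: tuple[float, float]


@dataclass(frozen=True)
class ROCCurveEstimate:
    """A fitted ROC curve with its area and provenance."""

    roc: Callable[[np.ndarray | float], np.ndarray | float]
    auc: float
    auc_interval: tuple[float, float] | None = None
    source_model: str = ""


@dataclass(frozen=True)
class CutoffResult:
    """One criterion's optimal cutoff and operating characteristics."""

    criterion: str
    cutoff: float
    sensitivity: float
    specificity: float
    criterion_value: float
    degenerate_flag: bool = False


def sensitivity_specificity(
    c: float | np.ndarray,
    f0: DistributionEstimate,
    f1: DistributionEstimate,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """se(c) = P[Y1 > c] = 1 - F1(c) and sp(c) = P[Y0 < c] = F0(c)."""
    return 1.0 - f1.cdf(c), f0.cdf(c)


def _coerce_status(values: pd.Series) -> pd.Series:
    levels = pd.unique(values.dropna())
    if len(levels) != 2:
        raise SchemaError(
            f"status column must take exactly two levels, found {list(levels)}"
        )
    try:
        numeric = pd.to_numeric(pd.Series(levels))
    except (ValueError, TypeError) as exc:
        raise SchemaError(
            f"status levels {list(levels)} are not mappable to 0/1"
        ) from exc
    if set(numeric) != {0, 1}:
        raise SchemaError(f"status levels {list(levels)} are not mappable to 0/1")
    mapping = dict(zip(levels, numeric.astype(int)))
    return values.map(mapping)


def validate_sample(
    raw_table: pd.DataFrame,
    direction: Direction | str = Direction.higher_is_diseased,
    covariates: Sequence[str] | None = None,
    biomarker_col: str = "biomarker",
    status_col: str = "status",
) -> BiomarkerSample:
    """Validate and normalize a per-subject table into a :class:`BiomarkerSample`.

    Rows with missing biomarker or status are dropped (with a logged count);
    when ``direction`` is ``lower_is_diseased`` the biomarker is negated so
    that the internal convention "higher indicates disease" always holds.
    """
    direction = Direction(direction)
    if biomarker_col not in raw_table.columns or status_col not in raw_table.columns:
        raise SchemaError(
            f"table must contain columns {biomarker_col!r} and {status_col!r}"
        )
    table = raw_table.copy()
    try:
        table[biomarker_col] = pd.to_numeric(table[biomarker_col])
    except (ValueError, TypeError) as exc:
        raise SchemaError("biomarker column is not numeric") from exc

    keep = table[biomarker_col].notna() & table[status_col].notna()
    if covariates:
        missing_cols = [c for c in covariates if c not in table.columns]
        if missing_cols:
            raise SchemaError(f"covariate columns not found: {missing_cols}")
        for c in covariates:
            table[c] = pd.to_numeric(table[c])
        keep &= table[list(covariates)].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("validate_sample: dropped %d incomplete rows", n_dropped)
    table = table.loc[keep]

    status = _coerce_status(table[status_col])
    y = table[biomarker_col].to_numpy(dtype=float)
    if direction is Direction.lower_is_diseased:
        y = -y
    mask1 = status.to_numpy() == 1
    y0, y1 = y[~mask1], y[mask1]
    if y0.size < 2 or y1.size < 2:
        raise UnusableInputError(
            f"need at least 2 subjects per group, got n0={y0.size}, n1={y1.size}"
        )
    x0 = x1 = None
    names: tuple[str, ...] = ()
    if covariates:
        x = table[list(covariates)].to_numpy(dtype=float)
        x0, x1 = x[~mask1], x[mask1]
        names = tuple(covariates)
    return BiomarkerSample(
        y0=y0, y1=y1, x0=x0, x1=x1, direction=direction, covariate_names=names
    )
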