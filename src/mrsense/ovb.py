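"""Omitted-variable-bias sensitivity algebra for partial regression coefficients.

The building block of the whole toolkit: given one fitted genetic
association (a partial regression coefficient of a trait on the genetic
instrument, with its standard error and residual degrees of freedom), these
functions answer "what would the estimate, SE and t-value have been had an
unmeasured variable W of postulated strength been included in the
regression?"  Strength is parameterized by two partial R² values:

* ``r2_wz`` — share of residual variance of the instrument Z explained by W
  (given observed covariates X);
* ``r2_wt`` — share of residual variance of the trait explained by W (given
  Z and X).

For a scalar W the adjustment formulas are exact; for multivariate W they
are conservative (worst case).  The robustness value RV_α is the minimal
equal strength (r2_wz = r2_wt) that makes the association insignificant at
level α; the extreme robustness value XRV_α is the minimal instrument-side
strength needed even if W explained all residual trait variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from scipy import stats

__all__ = [
    "AssociationSummary",
    "Direction",
    "SensitivityParams",
    "SensitivityStats",
    "partial_r2_from_t",
    "partial_f2_from_t",
    "adjusted_estimate",
    "adjusted_se",
    "adjusted_t",
    "robustness_value",
    "extreme_robustness_value",
    "sensitivity_stats",
    "critical_t",
]


class Direction(str, Enum):
    """Direction in which the hypothesized bias acts on the estimate."""

    toward_null = "toward_null"
    away_from_null = "away_from_null"


@dataclass(frozen=True)
class AssociationSummary:
    """One partial regression coefficient with its inferential companions.

    Parameters
    ----------
    estimate : float
        Point estimate (trait units per instrument unit).
    se : float
        Classical least-squares standard error, > 0.
    df : int
        Residual degrees of freedom of the fitted regression, >= 2.
    """

    estimate: float
    se: float
    df: int
    t_value: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if self.df < 2:
            raise ValueError(f"df must be >= 2, got {self.df}")
        t = self.estimate / self.se
        if self.t_value is None:
            object.__setattr__(self, "t_value", t)
        else:
            scale = max(abs(t), 1.0)
            if abs(self.t_value - t) > 1e-10 * scale:
                raise ValueError(
                    f"t_value {self.t_value} inconsistent with estimate/se = {t}"
                )

    def p_value(self, h0: float = 0.0) -> float:
        """Two-sided Student-t p-value against the point null ``h0``."""
        t = (self.estimate - h0) / self.se
        return 2.0 * stats.t.sf(abs(t), self.df)


@dataclass(frozen=True)
class SensitivityParams:
    """Hypothesized strength of the unmeasured variable W."""

    r2_wz: float
    r2_wt: float
    direction: Direction = Direction.toward_null

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_wz < 1.0:
            raise ValueError(f"r2_wz must lie in [0, 1), got {self.r2_wz}")
        if not 0.0 <= self.r2_wt <= 1.0:
            raise ValueError(f"r2_wt must lie in [0, 1], got {self.r2_wt}")
        object.__setattr__(self, "direction", Direction(self.direction))


@dataclass(frozen=True)
class SensitivityStats:
    """Routine-reporting sensitivity statistics for one association."""

    partial_r2: float
    f2: float
    rv_alpha: float
    xrv_alpha: float
    alpha: float


def critical_t(alpha: float, df: int) -> float:
    """Two-sided Student-t critical threshold t* at level ``alpha``."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if alpha == 1.0:
        return 0.0
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def partial_r2_from_t(t: float, df: int) -> float:
    """Partial R² implied by a t-value: t² / (t² + df).

    The inverse of Cohen's f² = R²/(1−R²) with f = t/√df.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return t * t / (t * t + df)


def partial_f2_from_t(t: float, df: int) -> float:
    """Partial Cohen's f² implied by a t-value: t² / df."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return t * t / df


def _bias(assoc: AssociationSummary, sens: SensitivityParams) -> float:
    # |bias| = se * sqrt(r2_wt * r2_wz / (1 - r2_wz) * df)
    return assoc.se * math.sqrt(
        sens.r2_wt * sens.r2_wz / (1.0 - sens.r2_wz) * assoc.df
    )


def adjusted_estimate(assoc: AssociationSummary, sens: SensitivityParams) -> float:
    """Estimate after adjusting for a W of the given strength.

    With ``toward_null`` the bias shrinks the estimate toward (and possibly
    through) zero; ``away_from_null`` pushes it outward.  Exact for scalar
    W, worst case for multivariate W.
    """
    bias = _bias(assoc, sens)
    sign = 1.0 if assoc.estimate >= 0 else -1.0
    if sens.direction is Direction.toward_null:
        return sign * (abs(assoc.estimate) - bias)
    return sign * (abs(assoc.estimate) + bias)


def adjusted_se(assoc: AssociationSummary, sens: SensitivityParams) -> float:
    """Standard error after adjusting for a W of the given strength."""
    if assoc.df < 2:
        raise ValueError("df must be >= 2 to spend one degree of freedom on W")
    return assoc.se * math.sqrt(
        (1.0 - sens.r2_wt) / (1.0 - sens.r2_wz) * assoc.df / (assoc.df - 1.0)
    )


def adjusted_t(
    assoc: AssociationSummary, sens: SensitivityParams, h0: float = 0.0
) -> float:
    """t-value of the W-adjusted estimate against ``h0``, at df−1."""
    num = adjusted_estimate(assoc, sens) - h0
    den = adjusted_se(assoc, sens)
    if den == 0.0:  # r2_wt = 1: W explains all residual trait variance
        return 0.0 if num == 0.0 else math.copysign(math.inf, num)
    return num / den


def robustness_value(t: float, df: int, alpha: float = 0.05) -> float:
    """Minimal equal strength (r2_wz = r2_wt) that flips significance.

    Any W with both partial R² values below RV_α cannot make the
    association insignificant at level α; any W with both above it can.
    Piecewise closed form in terms of f = |t|/√df and the rescaled critical
    threshold f*_α = t*_{α,df−1}/√(df−1).
    """
    if df < 2:
        raise ValueError(f"df must be >= 2, got {df}")
    f = abs(t) / math.sqrt(df)
    f_star = critical_t(alpha, df - 1) / math.sqrt(df - 1)
    f_alpha = f - f_star
    if f_alpha < 0.0:
        return 0.0
    if f_star == 0.0 or (f_star <= f < 1.0 / f_star):
        return 0.5 * (math.sqrt(f_alpha**4 + 4.0 * f_alpha**2) - f_alpha**2)
    return (f * f - f_star * f_star) / (1.0 + f * f)


def extreme_robustness_value(t: float, df: int, alpha: float = 0.05) -> float:
    """Minimal instrument-side strength when W explains all trait variance.

    At α = 1 this reduces to the partial R² of the association itself.
    """
    if df < 2:
        raise ValueError(f"df must be >= 2, got {df}")
    f = abs(t) / math.sqrt(df)
    f_star = critical_t(alpha, df - 1) / math.sqrt(df - 1)
    if f - f_star <= 0.0:
        return 0.0
    # (f^2 - f*^2)/(1 + f^2) rearranged so alpha = 1 reduces to the
    # partial R2 bit-for-bit
    return (t * t - df * f_star * f_star) / (t * t + df)


def sensitivity_stats(assoc: AssociationSummary, alpha: float = 0.05) -> SensitivityStats:
    """Bundle partial R², f², RV_α and XRV_α for one association."""
    f2 = partial_f2_from_t(assoc.t_value, assoc.df)
    return SensitivityStats(
        partial_r2=partial_r2_from_t(assoc.t_value, assoc.df),
        f2=f2,
        rv_alpha=robustness_value(assoc.t_value, assoc.df, alpha),
        xrv_alpha=extreme_robustness_value(assoc.t_value, assoc.df, alpha),
        alpha=alpha,
    )
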