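"""Anderson-Rubin inference and Fieller confidence sets for the MR ratio.

The MR estimand is the ratio of two genetic associations,
tau = beta_YZ|X / beta_DZ|X: the partial regression coefficient of the
outcome trait on the genetic instrument over that of the exposure trait,
both adjusting for observed covariates X.  The Anderson-Rubin (AR) test of
H0: tau = tau0 regresses Y - tau0*D on (Z, X) and tests the Z coefficient;
inverting it over tau0 yields Fieller's confidence set, a quadratic
inequality a*tau0^2 + b*tau0 + c <= 0 whose solution set is a bounded
interval, a union of two unbounded rays, or the whole real line.  The test
keeps its nominal size regardless of instrument strength.

Everything is computed by residualized least squares (Frisch-Waugh-Lovell),
so that coefficients, SEs and the coefficient covariance reproduce classical
multivariable OLS output exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ovb import AssociationSummary, critical_t

__all__ = [
    "MRData",
    "MRFit",
    "CIShape",
    "FiellerCI",
    "residualize",
    "drop_collinear",
    "fit_associations",
    "ar_test",
    "fieller_ci",
    "zero_null_equivalence",
    "prs_score",
    "DegenerateInstrumentError",
]

logger = logging.getLogger(__name__)

COLLINEARITY_TOL = 1e-9


class DegenerateInstrumentError(ValueError):
    """The instrument has no residual variance after removing X."""


@dataclass
class MRData:
    """Individual-level inputs for a single-instrument MR analysis.

    ``x`` is a covariate DataFrame that must include an intercept column;
    ``group_labels`` optionally tags each covariate with one of
    {ps, batch, hp, ind} (population structure, batch, pleiotropy proxy,
    individual characteristics) for benchmark selection.
    """

    y: np.ndarray
    d: np.ndarray
    z: np.ndarray
    x: pd.DataFrame
    group_labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.d = np.asarray(self.d, dtype=float).ravel()
        self.z = np.asarray(self.z, dtype=float).ravel()
        if not isinstance(self.x, pd.DataFrame):
            self.x = pd.DataFrame(np.asarray(self.x, dtype=float))
            self.x.columns = [f"x{i}" for i in range(self.x.shape[1])]
        n = len(self.y)
        if not (len(self.d) == len(self.z) == self.x.shape[0] == n):
            raise ValueError("y, d, z and x must have equal length")
        if n <= self.x.shape[1] + 2:
            raise ValueError("need n > p + 2 observations")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class MRFit:
    """The two fitted genetic associations from one dataset."""

    assoc_exposure: AssociationSummary
    assoc_outcome: AssociationSummary
    cov_betas: float
    df: int

    def __post_init__(self) -> None:
        bound = self.assoc_exposure.se * self.assoc_outcome.se
        if abs(self.cov_betas) > bound * (1.0 + 1e-8):
            raise ValueError("cov_betas violates Cauchy-Schwarz")

    @property
    def ratio(self) -> float:
        """Point estimate of the MR ratio tau."""
        return self.assoc_outcome.estimate / self.assoc_exposure.estimate


class CIShape(str, Enum):
    bounded = "bounded"
    union_unbounded = "union_unbounded"
    whole_line = "whole_line"


@dataclass(frozen=True)
class FiellerCI:
    """Fieller confidence set for the MR ratio.

    ``bounded``: [lower, upper].  ``union_unbounded``: (-inf, lower] union
    [upper, +inf) (a single ray when one endpoint is infinite).
    ``whole_line``: all reals.  ``quad`` holds the (a, b, c) coefficients of
    the defining inequality a*tau^2 + b*tau + c <= 0.
    """

    shape: CIShape
    lower: float
    upper: float
    alpha: float
    quad: tuple[float, float, float]

    def contains(self, tau0: float) -> bool:
        a, b, c = self.quad
        return a * tau0 * tau0 + b * tau0 + c <= 0.0


def drop_collinear(x: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
    """Keep a maximal left-to-right independent subset of columns.

    Deterministic: columns are scanned in order and a column is dropped iff
    it lies (numerically) in the span of the columns already kept.
    """
    x = np.asarray(x, dtype=float)
    keep: list[int] = []
    for j in range(x.shape[1]):
        col = x[:, j]
        if keep:
            basis = x[:, keep]
            coef, *_ = np.linalg.lstsq(basis, col, rcond=None)
            resid = col - basis @ coef
        else:
            resid = col
        scale = np.linalg.norm(col)
        if np.linalg.norm(resid) > COLLINEARITY_TOL * max(scale, 1.0):
            keep.append(j)
        else:
            label = names[j] if names is not None else f"column {j}"
            logger.warning("dropping collinear covariate %s", label)
    return x[:, keep]


def residualize(m: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Replace each column of ``m`` by its least-squares residual on ``x``."""
    m = np.asarray(m, dtype=float)
    squeeze = m.ndim == 1
    if squeeze:
        m = m[:, None]
    x = drop_collinear(x)
    coef, *_ = np.linalg.lstsq(x, m, rcond=None)
    out = m - x @ coef
    return out[:, 0] if squeeze else out


def _prepare(data: MRData) -> tuple[np.ndarray, int]:
    """Collinearity-pruned covariate matrix and its column count."""
    x = drop_collinear(data.x.to_numpy(dtype=float), list(data.x.columns))
    return x, x.shape[1]


def fit_associations(data: MRData) -> MRFit:
    """Fit beta_YZ|X and beta_DZ|X with their SEs and covariance.

    Uses Frisch-Waugh-Lovell residualization; SEs reproduce classical
    least-squares output with df = n - p - 1 (p counting covariate columns,
    including the intercept, after collinearity pruning).
    """
    x, p = _prepare(data)
    n = data.n
    df = n - p - 1
    z_perp = residualize(data.z, x)
    ss_z = float(z_perp @ z_perp)
    if ss_z <= COLLINEARITY_TOL * n:
        raise DegenerateInstrumentError(
            "instrument has no residual variance given the covariates"
        )
    beta_yz = float(z_perp @ data.y) / ss_z
    beta_dz = float(z_perp @ data.d) / ss_z
    zx = np.column_stack([data.z, x])
    resid = residualize(np.column_stack([data.y, data.d]), zx)
    e_y, e_d = resid[:, 0], resid[:, 1]
    var_yz = float(e_y @ e_y) / df / ss_z
    var_dz = float(e_d @ e_d) / df / ss_z
    cov = float(e_y @ e_d) / df / ss_z
    return MRFit(
        assoc_exposure=AssociationSummary(beta_dz, math.sqrt(var_dz), df),
        assoc_outcome=AssociationSummary(beta_yz, math.sqrt(var_yz), df),
        cov_betas=cov,
        df=df,
    )


def ar_statistic(tau0: float, fit: MRFit) -> float:
    """t-value of the Z coefficient in the regression of Y - tau0*D on (Z, X)."""
    phi = fit.assoc_outcome.estimate - tau0 * fit.assoc_exposure.estimate
    var = (
        fit.assoc_outcome.se**2
        + tau0 * tau0 * fit.assoc_exposure.se**2
        - 2.0 * tau0 * fit.cov_betas
    )
    return phi / math.sqrt(var)


def ar_test(
    tau0: float, data: MRData | MRFit, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Anderson-Rubin test of H0: tau = tau0.

    Returns ``(t_value, p_value, reject)``.  Accepts either raw data or an
    already-fitted :class:`MRFit` (the two are numerically identical).
    """
    fit = data if isinstance(data, MRFit) else fit_associations(data)
    t = ar_statistic(tau0, fit)
    p = 2.0 * stats.t.sf(abs(t), fit.df)
    t_star = critical_t(alpha, fit.df)
    return t, p, t * t > t_star * t_star


def fieller_ci(fit: MRFit, alpha: float = 0.05) -> FiellerCI:
    """Invert the AR test into Fieller's confidence set for the ratio."""
    t_star2 = critical_t(alpha, fit.df) ** 2
    by, bd = fit.assoc_outcome.estimate, fit.assoc_exposure.estimate
    vy, vd = fit.assoc_outcome.se**2, fit.assoc_exposure.se**2
    a = bd * bd - vd * t_star2
    b = 2.0 * (fit.cov_betas * t_star2 - by * bd)
    c = by * by - vy * t_star2
    quad = (a, b, c)
    disc = b * b - 4.0 * a * c
    if a > 0.0:
        # convex: the quadratic is <= 0 at the ratio point estimate, so the
        # discriminant is nonnegative and a bounded interval always exists
        assert disc >= 0.0, "convex Fieller quadratic with empty solution set"
        r = math.sqrt(disc)
        return FiellerCI(
            CIShape.bounded, (-b - r) / (2 * a), (-b + r) / (2 * a), alpha, quad
        )
    if a < 0.0:
        if disc > 0.0:
            r = math.sqrt(disc)
            lo, hi = sorted([(-b - r) / (2 * a), (-b + r) / (2 * a)])
            return FiellerCI(CIShape.union_unbounded, lo, hi, alpha, quad)
        return FiellerCI(CIShape.whole_line, -math.inf, math.inf, alpha, quad)
    # a == 0: linear inequality b*tau0 + c <= 0 (one-sided ray)
    if b > 0.0:
        return FiellerCI(CIShape.union_unbounded, -c / b, math.inf, alpha, quad)
    if b < 0.0:
        return FiellerCI(CIShape.union_unbounded, -math.inf, -c / b, alpha, quad)
    if c <= 0.0:
        return FiellerCI(CIShape.whole_line, -math.inf, math.inf, alpha, quad)
    raise AssertionError("degenerate Fieller quadratic with empty solution set")


def zero_null_equivalence(fit: MRFit, alpha: float = 0.05) -> tuple[bool, bool]:
    """Flags (MR zero-null rejected, outcome association significant).

    The two are always equal: the AR test of tau = 0 is exactly the t-test
    of the instrument-outcome association.  Both are returned for reporting.
    """
    mr_significant = not fieller_ci(fit, alpha).contains(0.0)
    t_star = critical_t(alpha, fit.df)
    outcome_significant = abs(fit.assoc_outcome.t_value) > t_star
    return mr_significant, outcome_significant


def prs_score(genotypes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted genotype score Z_i = sum_j w_j G_ij.

    Missing dosages (NaN) are mean-imputed per variant, with a log note.
    """
    g = np.asarray(genotypes, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    if g.ndim != 2 or g.shape[1] != w.shape[0]:
        raise ValueError(
            f"genotypes {g.shape} incompatible with {w.shape[0]} weights"
        )
    n_missing = int(np.isnan(g).sum())
    if n_missing:
        logger.info("mean-imputing %d missing dosages", n_missing)
        col_means = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g = g.copy()
        g[idx] = np.take(col_means, idx[1])
    return g @ w
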