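"""Benchmark bounds on the strength of unmeasured variables, and critical k.

Direct claims about the partial R² of an unmeasured W are hard to make;
relative claims are easier: "residual population stratification is at most
k times as strong as the 20 leading principal components".  Given an
observed benchmark covariate group Xj, the multipliers

    k_Z = R²_{ZW|X-j} / R²_{ZXj|X-j},   k_Y = R²_{TW|X-j Z} / R²_{TXj|X-j Z}

translate such a claim into an upper bound on (R²_{ZW|X}, R²_{TW|ZX}) for a
W orthogonal to the observed covariates, which can then be fed to the
adjustment formulas.  The "critical k" is the smallest multiple k (with
k_Z = k_Y = k) at which the worst-case bound explains away statistical
significance of the association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from . import ar
from .ovb import (
    AssociationSummary,
    Direction,
    SensitivityParams,
    adjusted_t,
    critical_t,
)

__all__ = [
    "Benchmark",
    "BoundResult",
    "InfeasibleBoundError",
    "benchmark_strength",
    "bound_r2",
    "critical_k",
]

logger = logging.getLogger(__name__)

_R2_CAP = 1.0 - 1e-12


class InfeasibleBoundError(ValueError):
    """The requested multiple implies an instrument-side partial R² >= 1."""


@dataclass(frozen=True)
class Benchmark:
    """Observed covariate-group strengths with hypothesized multipliers."""

    label: str
    r2_zxj: float
    r2_txj: float
    k_z: float = 1.0
    k_y: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r2_zxj", "r2_txj"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.k_z < 0 or self.k_y < 0:
            raise ValueError("k multipliers must be nonnegative")

    def scaled(self, k: float) -> "Benchmark":
        return Benchmark(self.label, self.r2_zxj, self.r2_txj, k_z=k, k_y=k)


@dataclass(frozen=True)
class BoundResult:
    """Worst-case strength pair for W, with the adjusted t at that point."""

    r2_wz_bound: float
    r2_wt_bound: float
    adjusted_t_at_bound: float
    label: str


def benchmark_strength(
    data: ar.MRData, trait: str, group: Sequence[str]
) -> tuple[float, float]:
    """Observed strength (r2_zxj, r2_txj) of a covariate group.

    Z-side: partial R² of the group with the instrument given the remaining
    covariates.  Trait-side: partial R² of the group with the chosen trait
    (``"exposure"`` for D, ``"outcome"`` for Y) given Z and the remaining
    covariates.  Groups are treated jointly via nested-RSS partial R².
    """
    if trait not in ("exposure", "outcome"):
        raise ValueError(f"trait must be 'exposure' or 'outcome', got {trait!r}")
    group = list(group)
    if not group:
        raise ValueError("benchmark group must be nonempty")
    missing = [g for g in group if g not in data.x.columns]
    if missing:
        raise ValueError(f"benchmark columns not in covariates: {missing}")
    others = [c for c in data.x.columns if c not in group]
    if not others:
        raise ValueError("benchmark group may not span all covariates")

    x_minus = ar.drop_collinear(data.x[others].to_numpy(float), others)
    grp = data.x[group].to_numpy(float)
    # joint group R2: residualize group on X_-j, then nested RSS
    t_vec = data.d if trait == "exposure" else data.y

    def nested_r2(target: np.ndarray, conditioning: np.ndarray) -> float:
        base = np.asarray(conditioning, float)
        full = ar.drop_collinear(np.column_stack([base, grp]))
        r_red = ar.residualize(target, base)
        r_full = ar.residualize(target, full)
        rss_red = float(r_red @ r_red)
        rss_full = float(r_full @ r_full)
        if rss_red <= 0.0:
            return 0.0
        return max(0.0, (rss_red - rss_full) / rss_red)

    r2_zxj = nested_r2(data.z, x_minus)
    r2_txj = nested_r2(t_vec, np.column_stack([data.z[:, None], x_minus]))
    return r2_zxj, r2_txj


def bound_r2(bench: Benchmark, assoc: AssociationSummary | None = None) -> BoundResult:
    """Worst-case (r2_wz, r2_wt) for a W at the benchmark's multiples.

    Instrument side: R²_{ZW|X} = k_Z · f²_{ZXj|X-j}.  Trait side:
    R²_{TW|ZX} <= η² · f²_{TXj|X-j Z} with the scalar η built from k_Y, k_Z
    and the benchmark's instrument-side strength; capped at 1.  If an
    association is supplied, the worst-case (toward-null) adjusted t at the
    bound point is attached.
    """
    f2_z = bench.r2_zxj / (1.0 - bench.r2_zxj)
    r2_wz = bench.k_z * f2_z
    if r2_wz >= 1.0:
        raise InfeasibleBoundError(
            f"benchmark {bench.label!r}: k_z={bench.k_z} implies an "
            f"instrument-side partial R2 of {r2_wz:.3f} >= 1"
        )
    # eta scalar for the trait-side bound (worst-case alignment of W with
    # the benchmark given Z): s is the implied R2 of W with Xj given X, Z
    s = bench.k_z * bench.r2_zxj**2 / (
        (1.0 - bench.k_z * bench.r2_zxj) * (1.0 - bench.r2_zxj)
    )
    if s >= 1.0:
        raise InfeasibleBoundError(
            f"benchmark {bench.label!r}: infeasible trait-side bound (s={s:.3f})"
        )
    eta = (math.sqrt(bench.k_y) + math.sqrt(s)) / math.sqrt(1.0 - s)
    f2_t = bench.r2_txj / (1.0 - bench.r2_txj)
    r2_wt = min(eta * eta * f2_t, 1.0)
    if assoc is not None:
        t_at = adjusted_t(
            assoc, SensitivityParams(min(r2_wz, _R2_CAP), r2_wt, Direction.toward_null)
        )
    else:
        t_at = math.nan
    return BoundResult(r2_wz, r2_wt, t_at, bench.label)


def _k_max(bench_unit: Benchmark) -> float:
    """Largest multiple keeping the instrument-side bound below 1."""
    f2_z = bench_unit.r2_zxj / (1.0 - bench_unit.r2_zxj)
    if f2_z <= 0.0:
        return math.inf
    return (1.0 - 1e-9) / f2_z


def critical_k(
    assoc: AssociationSummary, bench_unit: Benchmark, alpha: float = 0.05
) -> float:
    """Smallest k >= 0 at which the k-times-benchmark bound kills significance.

    Sets k_Z = k_Y = k, scales the benchmark, and bisects on the worst-case
    adjusted t.  Returns 0 if the association is already insignificant at
    the bound origin, and +inf if no feasible multiple suffices.
    """
    t_star = critical_t(alpha, assoc.df - 1)
    sign = 1.0 if assoc.estimate >= 0 else -1.0

    def signed_adjusted_t(k: float) -> float:
        res = bound_r2(bench_unit.scaled(k), assoc)
        return sign * res.adjusted_t_at_bound

    if signed_adjusted_t(0.0) <= t_star:
        return 0.0
    k_hi = _k_max(bench_unit)
    if math.isinf(k_hi):
        logger.info("benchmark %r has zero instrument-side strength", bench_unit.label)
        return math.inf
    # shrink just inside feasibility; signed adjusted t is monotone
    # nonincreasing in k (toward-null bias grows with both bounds)
    k_hi = k_hi * (1.0 - 1e-9)
    # coarse scan for the FIRST crossing (the adjusted t need not be
    # globally monotone in k), then bisect within that bracket
    grid = np.linspace(0.0, k_hi, 257)
    vals = np.array([signed_adjusted_t(k) for k in grid])
    below = np.nonzero(vals <= t_star)[0]
    if below.size == 0:
        logger.info(
            "no feasible multiple of benchmark %r explains away significance",
            bench_unit.label,
        )
        return math.inf
    i = below[0]
    return float(
        optimize.brentq(
            lambda k: signed_adjusted_t(k) - t_star,
            grid[i - 1],
            grid[i],
            xtol=1e-6,
        )
    )
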