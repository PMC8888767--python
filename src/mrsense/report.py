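"""Minimal sensitivity report and adjusted-t contour grids/plots.

The minimal report collects, for the exposure-side and outcome-side genetic
associations: the estimate, its Fieller/AR confidence set and p-value, the
partial R² and robustness value, plus the benchmark bound table and the two
decomposition flags (weak instrument iff the Fieller set is unbounded; MR
zero-null significance iff the instrument-outcome association is
significant).  Contour grids tabulate the W-adjusted t-value over a grid of
hypothesized strength pairs and can be rendered as contour plots with
benchmark bounds overlaid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import ar, bounds
from .ovb import (
    AssociationSummary,
    SensitivityParams,
    adjusted_t,
    critical_t,
    partial_r2_from_t,
    robustness_value,
)

__all__ = [
    "GridSpec",
    "ContourGrid",
    "SensitivityReport",
    "contour_grid",
    "minimal_report",
    "render_plot",
]


@dataclass(frozen=True)
class GridSpec:
    """Axis layout for a contour grid; limits are partial R² fractions."""

    n_points: int = 100
    r2_wz_limit: float | None = None
    r2_wt_limit: float | None = None

    def limits_for(self, assoc: AssociationSummary) -> tuple[float, float]:
        """Default limit min(0.4, 20x partial R²), adapted per association."""
        auto = min(0.4, 20.0 * partial_r2_from_t(assoc.t_value, assoc.df))
        auto = max(auto, 1e-4)
        wz = self.r2_wz_limit if self.r2_wz_limit is not None else auto
        wt = self.r2_wt_limit if self.r2_wt_limit is not None else auto
        if not (0.0 < wz < 1.0):
            raise ValueError(f"instrument-axis limit must lie in (0, 1), got {wz}")
        if not (0.0 < wt <= 1.0):
            raise ValueError(f"trait-axis limit must lie in (0, 1], got {wt}")
        return wz, wt


@dataclass
class ContourGrid:
    """Adjusted t-values over hypothesized strength pairs.

    ``t_values[i, j]`` is the adjusted t at
    (r2_wz_axis[i], r2_wt_axis[j]).
    """

    r2_wz_axis: np.ndarray
    r2_wt_axis: np.ndarray
    t_values: np.ndarray
    critical_level: float
    benchmark_points: list[tuple[str, float, float, float]] = field(
        default_factory=list
    )


def contour_grid(
    assoc: AssociationSummary,
    grid_spec: GridSpec | None = None,
    benchmarks: Sequence[bounds.BoundResult] = (),
    alpha: float = 0.05,
) -> ContourGrid:
    """Tabulate the W-adjusted t over a grid of strength pairs."""
    spec = grid_spec or GridSpec()
    wz_lim, wt_lim = spec.limits_for(assoc)
    wz = np.linspace(0.0, wz_lim, spec.n_points)
    wt = np.linspace(0.0, wt_lim, spec.n_points)
    t_values = np.empty((spec.n_points, spec.n_points))
    for i, rz in enumerate(wz):
        for j, rt in enumerate(wt):
            t_values[i, j] = adjusted_t(assoc, SensitivityParams(rz, rt))
    points = [
        (b.label, b.r2_wz_bound, b.r2_wt_bound, b.adjusted_t_at_bound)
        for b in benchmarks
    ]
    return ContourGrid(wz, wt, t_values, critical_t(alpha, assoc.df - 1), points)


@dataclass
class SensitivityReport:
    """Minimal sensitivity reporting for one MR analysis."""

    alpha: float
    ratio_estimate: float
    ci_shape: str
    ci_lower: float
    ci_upper: float
    ar_p_value: float
    exposure: dict
    outcome: dict
    bound_table: list[dict]
    weak_instrument: bool
    mr_significant: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "SensitivityReport":
        return cls(**json.loads(text))


def _assoc_row(assoc: AssociationSummary, alpha: float) -> dict:
    return {
        "estimate": assoc.estimate,
        "se": assoc.se,
        "t_value": assoc.t_value,
        "p_value": assoc.p_value(),
        "partial_r2": partial_r2_from_t(assoc.t_value, assoc.df),
        "rv_alpha": robustness_value(assoc.t_value, assoc.df, alpha),
    }


def minimal_report(
    data: ar.MRData,
    benchmarks: Sequence[tuple[str, Sequence[str], float]] = (),
    alpha: float = 0.05,
) -> SensitivityReport:
    """Build the minimal sensitivity report from individual-level data.

    ``benchmarks`` is a sequence of (label, covariate columns, k multiple);
    each produces one bound row per trait side.
    """
    fit = ar.fit_associations(data)
    ci = ar.fieller_ci(fit, alpha)
    _, ar_p, _ = ar.ar_test(0.0, fit, alpha)
    mr_significant, outcome_significant = ar.zero_null_equivalence(fit, alpha)
    assert mr_significant == outcome_significant
    bound_rows = []
    for label, cols, k in benchmarks:
        for trait, assoc in (
            ("exposure", fit.assoc_exposure),
            ("outcome", fit.assoc_outcome),
        ):
            r2_zxj, r2_txj = bounds.benchmark_strength(data, trait, cols)
            bench = bounds.Benchmark(label, r2_zxj, r2_txj, k_z=k, k_y=k)
            res = bounds.bound_r2(bench, assoc)
            bound_rows.append(
                {
                    "label": f"{k:g}x {label}",
                    "trait": trait,
                    "r2_wz_bound": res.r2_wz_bound,
                    "r2_wt_bound": res.r2_wt_bound,
                    "adjusted_t_at_bound": res.adjusted_t_at_bound,
                    "critical_k": bounds.critical_k(assoc, bench.scaled(1.0), alpha),
                }
            )
    return SensitivityReport(
        alpha=alpha,
        ratio_estimate=fit.ratio,
        ci_shape=ci.shape.value,
        ci_lower=ci.lower,
        ci_upper=ci.upper,
        ar_p_value=ar_p,
        exposure=_assoc_row(fit.assoc_exposure, alpha),
        outcome=_assoc_row(fit.assoc_outcome, alpha),
        bound_table=bound_rows,
        weak_instrument=ci.shape is not ar.CIShape.bounded,
        mr_significant=mr_significant,
    )


def render_plot(grid: ContourGrid, out_path: str | Path) -> Path:
    """Render a labeled contour plot; writes a delimited grid sidecar too.

    The critical contour at t* is drawn as a red dashed line, the
    unadjusted association as a black triangle at the origin, and benchmark
    bounds as red diamonds.  The sidecar ``<out>.grid.csv`` holds the t
    matrix with axis values as row/column headers.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    wz, wt = np.meshgrid(grid.r2_wz_axis, grid.r2_wt_axis, indexing="ij")
    finite = grid.t_values[np.isfinite(grid.t_values)]
    levels = sorted(
        set(np.round(np.linspace(finite.min(), finite.max(), 12), 2)) - {0.0}
    )
    cs = ax.contour(wz, wt, grid.t_values, levels=levels, colors="grey", linewidths=0.7)
    ax.clabel(cs, inline=True, fontsize=7, fmt="%.2f")
    for lev, style in ((0.0, "dotted"), (grid.critical_level, "dashed")):
        if finite.min() < lev < finite.max():
            ccrit = ax.contour(
                wz, wt, grid.t_values, levels=[lev], colors="red",
                linestyles=style, linewidths=1.2,
            )
            ax.clabel(ccrit, inline=True, fontsize=8, fmt="t = %.2f")
    ax.plot([0.0], [0.0], marker="^", color="black", markersize=9, zorder=5)
    for label, rz, rt, t_at in grid.benchmark_points:
        ax.plot([rz], [rt], marker="D", color="red", markersize=6, zorder=5)
        ax.annotate(
            f"{label}\n({t_at:.2f})", (rz, rt), fontsize=7,
            textcoords="offset points", xytext=(4, 4),
        )
    ax.set_xlabel("partial $R^2$ of W with the genetic instrument")
    ax.set_ylabel("partial $R^2$ of W with the trait")
    fmt = matplotlib.ticker.FuncFormatter(lambda v, _: f"{100 * v:.2g}%")
    ax.xaxis.set_major_formatter(fmt)
    ax.yaxis.set_major_formatter(fmt)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    sidecar = out_path.with_suffix(out_path.suffix + ".grid.csv")
    header = ",".join(["r2_wz\\r2_wt"] + [f"{v:.10g}" for v in grid.r2_wt_axis])
    rows = [
        f"{rz:.10g}," + ",".join(f"{t:.10g}" for t in grid.t_values[i])
        for i, rz in enumerate(grid.r2_wz_axis)
    ]
    sidecar.write_text(header + "\n" + "\n".join(rows) + "\n")
    return out_path
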