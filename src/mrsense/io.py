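"""File input, configuration, and table plumbing.

Phenotype data arrive as delimited text (comma or tab, autodetected) with a
header; genotypes as plain dosage tables plus a variant/weight file for
building the polygenic score.  Configuration is a YAML file mapping columns
to roles and covariate groups ({ps, batch, hp, ind}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import ar

__all__ = [
    "AnalysisConfig",
    "BenchmarkSpec",
    "read_delimited",
    "read_phenotype_table",
    "read_dosage_matrix",
    "read_weights",
    "align_dosages_weights",
]

logger = logging.getLogger(__name__)

COVARIATE_GROUPS = ("ps", "batch", "hp", "ind")


@dataclass(frozen=True)
class BenchmarkSpec:
    """One benchmark: a label, covariate columns (or a group tag), multiples."""

    label: str
    columns: tuple[str, ...] = ()
    group: str | None = None
    k: tuple[float, ...] = (1.0,)

    def resolve_columns(self, group_labels: Mapping[str, str]) -> list[str]:
        if self.columns:
            return list(self.columns)
        if self.group is None:
            raise ValueError(f"benchmark {self.label!r} names no columns or group")
        cols = [c for c, g in group_labels.items() if g == self.group]
        if not cols:
            raise ValueError(
                f"benchmark {self.label!r}: no covariates tagged {self.group!r}"
            )
        return cols


@dataclass
class AnalysisConfig:
    """Configuration for a single-instrument sensitivity analysis."""

    phenotype: str
    outcome: str
    exposure: str
    covariates: dict[str, str]
    instrument: str | None = None
    dosages: str | None = None
    weights: str | None = None
    dosage_orientation: str = "samples_by_variants"
    alpha: float = 0.05
    benchmarks: list[BenchmarkSpec] = field(default_factory=list)
    grid_points: int = 100
    r2_wz_limit: float | None = None
    r2_wt_limit: float | None = None
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for col, grp in self.covariates.items():
            if grp not in COVARIATE_GROUPS:
                raise ValueError(
                    f"covariate {col!r} has unknown group {grp!r}; "
                    f"expected one of {COVARIATE_GROUPS}"
                )
        if self.instrument is None and not (self.dosages and self.weights):
            raise ValueError(
                "config must name either an instrument column or dosage "
                "and weight files"
            )
        self.benchmarks = [
            b
            if isinstance(b, BenchmarkSpec)
            else BenchmarkSpec(
                label=b["label"],
                columns=tuple(b.get("columns", ())),
                group=b.get("group"),
                k=tuple(b.get("k", (1.0,))),
            )
            for b in self.benchmarks
        ]
        for b in self.benchmarks:
            if any(kk < 0 for kk in b.k):
                raise ValueError(f"benchmark {b.label!r}: k multiples must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        benches = [
            BenchmarkSpec(
                label=b["label"],
                columns=tuple(b.get("columns", ())),
                group=b.get("group"),
                k=tuple(b.get("k", (1.0,))),
            )
            for b in raw.pop("benchmarks", [])
        ]
        grid = raw.pop("grid", {}) or {}
        return cls(
            benchmarks=benches,
            grid_points=grid.get("n_points", 100),
            r2_wz_limit=grid.get("r2_wz_limit"),
            r2_wt_limit=grid.get("r2_wt_limit"),
            **raw,
        )


def read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with header, dialect autodetected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    return df


def read_phenotype_table(path: str | Path, config: AnalysisConfig) -> ar.MRData:
    """Build :class:`MRData` from a delimited phenotype table.

    Rows with any missing value among the used columns are dropped (count
    logged); an intercept column is prepended to the covariates.  The
    instrument is either a named column or a polygenic score built from the
    configured dosage and weight files.
    """
    df = read_delimited(path)
    needed = [config.outcome, config.exposure, *config.covariates]
    if config.instrument is not None:
        needed.insert(2, config.instrument)
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise KeyError(f"phenotype table lacks columns: {missing_cols}")

    if config.instrument is None:
        dosages = read_dosage_matrix(config.dosages, config.dosage_orientation)
        weights = read_weights(config.weights)
        g, w = align_dosages_weights(dosages, weights)
        if g.shape[0] != len(df):
            raise ValueError(
                f"dosage matrix has {g.shape[0]} samples but phenotype "
                f"table has {len(df)} rows"
            )
        df = df.assign(_prs=ar.prs_score(g.to_numpy(float), w.to_numpy(float)))
        instrument = "_prs"
    else:
        instrument = config.instrument

    used = df[[config.outcome, config.exposure, instrument, *config.covariates]]
    mask = used.notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.warning("dropping %d rows with missing values", dropped)
    used = used.loc[mask]
    x = pd.DataFrame({"intercept": np.ones(len(used))}, index=used.index)
    x = pd.concat([x, used[list(config.covariates)]], axis=1)
    labels = {"intercept": "ind", **config.covariates}
    return ar.MRData(
        y=used[config.outcome].to_numpy(float),
        d=used[config.exposure].to_numpy(float),
        z=used[instrument].to_numpy(float),
        x=x.astype(float),
        group_labels=labels,
    )


def read_dosage_matrix(
    path: str | Path, orientation: str = "samples_by_variants"
) -> pd.DataFrame:
    """Read a dosage table; returns samples x variants with variant-id columns."""
    df = read_delimited(path)
    if orientation == "variants_by_samples":
        df = df.set_index(df.columns[0]).T.reset_index(drop=True)
        df.columns.name = None
    elif orientation != "samples_by_variants":
        raise ValueError(f"unknown dosage orientation {orientation!r}")
    return df


def read_weights(path: str | Path) -> pd.Series:
    """Read a variant/weight file (two columns: variant id, weight)."""
    df = read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError("weights file needs variant-id and weight columns")
    return pd.Series(
        df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str), name="weight"
    )


def align_dosages_weights(
    dosages: pd.DataFrame, weights: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Align dosage columns and weights by variant id, dropping unmatched."""
    dosage_ids = [str(c) for c in dosages.columns]
    common = [v for v in dosage_ids if v in weights.index]
    n_dropped = (len(dosage_ids) - len(common)) + int(
        (~weights.index.isin(common)).sum()
    )
    if not common:
        raise ValueError("no overlapping variants between dosages and weights")
    if n_dropped:
        logger.warning("dropping %d unmatched variants", n_dropped)
    dosages = dosages.copy()
    dosages.columns = dosage_ids
    return dosages[common], weights.loc[common]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
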