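"""Synthetic fixture generation with known ground truth.

Writes small, fully self-contained datasets to disk — a phenotype table, a
dosage matrix with score weights, and a JSON sidecar recording the true
causal effect and the planted strength of the unmeasured variable — so
every analysis path can be exercised and checked against known answers
without any external data.

Three kinds mirror the canonical validity threats:

* ``valid_iv`` — the score is a valid instrument given the observed
  covariates (confounding between exposure and outcome only, which IV
  analysis tolerates);
* ``confounded`` — an unmeasured population-structure variable W loads on
  the instrument and on the outcome;
* ``pleiotropic`` — W is a downstream trait of the same variants (a
  horizontal pleiotropic pathway to the outcome).

The W column is written to the phenotype table as ``w_true`` (ground truth
for oracle checks; it is *not* part of the observed covariate set).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("valid_iv", "confounded", "pleiotropic")

_N_VARIANTS = 5
_WEIGHTS = np.array([0.30, 0.25, 0.20, 0.15, 0.10])
# var of the raw score: sum(w^2) * var(Binom(2,1/3)) = sum(w^2) * 4/9
_SCORE_SD = float(np.sqrt(_WEIGHTS @ _WEIGHTS * 4.0 / 9.0))

_B_Z = 0.5  # instrument -> exposure
_A_CONF = 0.33  # W -> instrument loading (confounded kind)
_C_CONF = 1.0  # W -> outcome loading (confounded kind)
_PHI_HP = 0.5  # score-shared loading of W (pleiotropic kind)
_GAMMA_HP = 0.6  # W -> outcome loading (pleiotropic kind)


def _planted_strengths(kind: str, tau: float) -> tuple[float, float]:
    """Population partial R² of W with the instrument and with the outcome.

    Derived from the linear-Gaussian fixture model with a unit-variance
    standardized score: the trait-side value conditions on the instrument,
    and the residual outcome noise is var((1+tau)U + tau*eps_D + eps_Y)
    = (1+tau)^2 + tau^2 + 1.
    """
    noise = (1.0 + tau) ** 2 + tau**2 + 1.0
    if kind == "valid_iv":
        return 0.0, 0.0
    if kind == "confounded":
        r2_wz = _A_CONF**2 / (1.0 + _A_CONF**2)
        var_w_given_z = 1.0 / (1.0 + _A_CONF**2)
        num = _C_CONF**2 * var_w_given_z
        return r2_wz, num / (num + noise)
    if kind == "pleiotropic":
        r2_wz = _PHI_HP**2 / (1.0 + _PHI_HP**2)
        num = _GAMMA_HP**2  # var(W | Z) = var(eps_W) = 1
        return r2_wz, num / (num + noise)
    raise ValueError(f"unknown fixture kind {kind!r}")


def generate_fixture(
    kind: str,
    n: int,
    seed: int,
    out_dir: str | Path,
    tau: float = 0.1,
) -> dict:
    """Write a synthetic dataset with known ground truth; returns the sidecar.

    Files: ``phenotype.csv`` (y, d, z, covariates, w_true),
    ``dosages.csv`` (samples x variants), ``weights.csv``,
    ``fixture.json``.  Byte-identical output for identical arguments.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"kind must be one of {FIXTURE_KINDS}, got {kind!r}")
    if n < 50:
        raise ValueError("need n >= 50")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    g = rng.binomial(2, 1.0 / 3.0, size=(n, _N_VARIANTS)).astype(float)
    score = (g - 2.0 / 3.0) @ _WEIGHTS / _SCORE_SD  # standardized PRS
    age = rng.normal(55.0, 8.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    pc1 = rng.standard_normal(n)
    u = rng.standard_normal(n)

    if kind == "valid_iv":
        w = np.zeros(n)
        z = score
        y_extra = 0.0
    elif kind == "confounded":
        w = rng.standard_normal(n)
        z = score + _A_CONF * w
        y_extra = _C_CONF * w
    else:  # pleiotropic
        w = _PHI_HP * score + rng.standard_normal(n)
        z = score
        y_extra = _GAMMA_HP * w

    d = _B_Z * z + 0.01 * age + 0.2 * pc1 + u + rng.standard_normal(n)
    y = tau * d + 0.2 * pc1 + y_extra + u + rng.standard_normal(n)

    pheno = pd.DataFrame(
        {"y": y, "d": d, "z": z, "age": age, "sex": sex, "pc1": pc1, "w_true": w}
    )
    pheno.to_csv(out_dir / "phenotype.csv", index=False, float_format="%.10g")
    dos = pd.DataFrame(g, columns=[f"v{j + 1}" for j in range(_N_VARIANTS)])
    dos.to_csv(out_dir / "dosages.csv", index=False, float_format="%g")
    pd.DataFrame(
        {"variant": dos.columns, "weight": _WEIGHTS / _SCORE_SD}
    ).to_csv(out_dir / "weights.csv", index=False, float_format="%.10g")

    r2_wz, r2_wt = _planted_strengths(kind, tau)
    sidecar = {
        "kind": kind,
        "n": n,
        "seed": seed,
        "tau": tau,
        "planted": {"r2_wz": r2_wz, "r2_wt": r2_wt},
        "columns": {
            "outcome": "y",
            "exposure": "d",
            "instrument": "z",
            "covariates": {"age": "ind", "sex": "ind", "pc1": "ps"},
            "unmeasured": "w_true",
        },
    }
    (out_dir / "fixture.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar
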