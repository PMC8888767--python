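import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import mrsense as m


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def partial_r2_of(target, var, controls):
    """Oracle partial R² of ``var`` with ``target`` given ``controls``."""
    res = sm.OLS(target, np.column_stack([var, controls])).fit()
    return res.tvalues[0] ** 2 / (res.tvalues[0] ** 2 + res.df_resid)


def make_mrdata(rng, n=200, beta_z=0.5, tau=0.3, p_extra=2, confound=1.0):
    """Random single-instrument dataset with intercept + noise covariates."""
    x = pd.DataFrame({"intercept": np.ones(n)})
    for j in range(p_extra):
        x[f"x{j + 1}"] = rng.standard_normal(n)
    z = rng.standard_normal(n)
    u = rng.standard_normal(n)
    d = beta_z * z + confound * u + x.iloc[:, 1:].sum(axis=1).to_numpy() * 0.3 + rng.standard_normal(n)
    y = tau * d + confound * u + rng.standard_normal(n)
    return m.MRData(y=y, d=d, z=z, x=x)


def random_mrfit(rng, df=500):
    """Random MRFit with a valid (Cauchy-Schwarz) coefficient covariance."""
    se_d = rng.uniform(0.02, 0.3)
    se_y = rng.uniform(0.02, 0.3)
    rho = rng.uniform(-0.9, 0.9)
    return m.MRFit(
        assoc_exposure=m.AssociationSummary(rng.normal(0, 0.5), se_d, df),
        assoc_outcome=m.AssociationSummary(rng.normal(0, 0.5), se_y, df),
        cov_betas=rho * se_d * se_y,
        df=df,
    )
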