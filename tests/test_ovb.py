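"""Omitted-variable-bias algebra: closed forms vs brute-force regressions."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import mrsense as m
from mrsense.ovb import critical_t, partial_f2_from_t


@pytest.mark.parametrize(
    "t, df, expected",
    [
        (0.0, 100, 0.0),
        (2.0, 100, 4.0 / 104.0),
        (math.sqrt(50), 50, 0.5),  # f^2 = 1 by construction
    ],
)
def test_partial_r2_from_t(t, df, expected):
    assert m.partial_r2_from_t(t, df) == pytest.approx(expected, rel=1e-12)


def test_partial_r2_inverse_relation():
    r2 = m.partial_r2_from_t(2.7, 83)
    f2 = partial_f2_from_t(2.7, 83)
    assert f2 == pytest.approx(r2 / (1 - r2), rel=1e-12)


def test_partial_r2_rejects_bad_df():
    with pytest.raises(ValueError):
        m.partial_r2_from_t(1.0, 0)


class TestAdjustment:
    assoc = m.AssociationSummary(0.8, 0.1, 120)

    def test_zero_strength_leaves_estimate(self):
        s = m.SensitivityParams(0.0, 0.0)
        assert m.adjusted_estimate(self.assoc, s) == self.assoc.estimate
        assert m.adjusted_se(self.assoc, s) == pytest.approx(
            self.assoc.se * math.sqrt(120 / 119)
        )
        assert m.adjusted_t(self.assoc, s) == pytest.approx(
            self.assoc.t_value * math.sqrt(119 / 120)
        )

    def test_extreme_scenario_eliminates_estimate(self):
        # W explaining all trait variance and exactly partial-R2 of the
        # instrument brings the estimate to zero: bias = se*f*sqrt(df) = est
        r2 = m.partial_r2_from_t(self.assoc.t_value, self.assoc.df)
        s = m.SensitivityParams(r2, 1.0)
        assert m.adjusted_estimate(self.assoc, s) == pytest.approx(0.0, abs=1e-12)
        assert m.adjusted_t(self.assoc, s) == 0.0

    def test_equal_r2_cancels_in_se(self):
        for x in (0.1, 0.5, 0.9):
            s = m.SensitivityParams(x, x)
            assert m.adjusted_se(self.assoc, s) == pytest.approx(
                self.assoc.se * math.sqrt(120 / 119)
            )

    def test_away_from_null_grows_magnitude(self):
        s = m.SensitivityParams(0.1, 0.2, m.Direction.away_from_null)
        assert abs(m.adjusted_estimate(self.assoc, s)) > abs(self.assoc.estimate)

    def test_rejects_r2_wz_of_one(self):
        with pytest.raises(ValueError):
            m.SensitivityParams(1.0, 0.5)


def _restricted_and_full(rng, n=80):
    """Dataset plus restricted (no-W) and full (with-W) regressions."""
    x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    z = rng.standard_normal(n) + x[:, 1]
    w = rng.standard_normal(n) + rng.uniform(-0.8, 0.8) * z
    y = (
        rng.uniform(-1, 1) * z
        + rng.uniform(-1.5, 1.5) * w
        + x @ np.array([0.0, 1.0, 0.5])
        + rng.standard_normal(n)
    )
    restricted = sm.OLS(y, np.column_stack([z, x])).fit()
    full = sm.OLS(y, np.column_stack([z, w, x])).fit()
    return restricted, full


def test_adjustment_matches_regression_including_w():
    """The closed forms reproduce the coefficient and SE of the regression
    that literally includes the constructed scalar W, to 1e-8 relative."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        restricted, full = _restricted_and_full(rng)
        assoc = m.AssociationSummary(
            restricted.params[0], restricted.bse[0], int(restricted.df_resid)
        )
        zw = sm.OLS(
            np.asarray(full.model.exog[:, 0]),  # z
            full.model.exog[:, 1:],  # w, x
        ).fit()
        r2_wz = zw.tvalues[0] ** 2 / (zw.tvalues[0] ** 2 + zw.df_resid)
        r2_wt = full.tvalues[1] ** 2 / (full.tvalues[1] ** 2 + full.df_resid)
        candidates = [
            m.adjusted_estimate(assoc, m.SensitivityParams(r2_wz, r2_wt, d))
            for d in (m.Direction.toward_null, m.Direction.away_from_null)
        ]
        # the bias formula fixes the magnitude; the data decide the sign
        assert min(abs(c - full.params[0]) for c in candidates) < 1e-8 * max(
            abs(full.params[0]), 1e-2
        )
        s = m.SensitivityParams(r2_wz, r2_wt)
        assert m.adjusted_se(assoc, s) == pytest.approx(full.bse[0], rel=1e-8)


class TestRobustnessValue:
    def test_insignificant_association_has_zero_rv(self):
        assert m.robustness_value(1.0, 500, 0.05) == 0.0
        assert m.extreme_robustness_value(1.0, 500, 0.05) == 0.0

    @pytest.mark.parametrize(
        "t, df, alpha", [(10, 1000, 0.05), (3, 100, 0.05), (5, 50, 0.01)]
    )
    def test_rv_fixed_point(self, t, df, alpha):
        """|adjusted_t(RV, RV)| hits the critical threshold within 1e-6."""
        rv = m.robustness_value(t, df, alpha)
        assoc = m.AssociationSummary(t * 0.1, 0.1, df)
        at = m.adjusted_t(assoc, m.SensitivityParams(rv, rv))
        assert abs(abs(at) - critical_t(alpha, df - 1)) < 1e-6

    def test_rv_matches_root_finder(self):
        """RV agrees with numerically solving |adjusted_t(r, r)| = t*."""
        from scipy import optimize

        t, df, alpha = 10.0, 1000, 0.05
        assoc = m.AssociationSummary(t, 1.0, df)
        tstar = critical_t(alpha, df - 1)
        # the equal-strength diagonal fully eliminates the estimate at the
        # alpha=1 robustness value, where the adjusted t is 0 < t*
        elimination = m.robustness_value(t, df, 1.0)
        root = optimize.brentq(
            lambda r: abs(m.adjusted_t(assoc, m.SensitivityParams(r, r))) - tstar,
            1e-12,
            elimination,
            xtol=1e-12,
        )
        assert m.robustness_value(t, df, alpha) == pytest.approx(root, abs=1e-9)

    def test_rv_alpha_one_middle_branch_arithmetic(self):
        f = 0.3
        expected = 0.5 * (math.sqrt(f**4 + 4 * f**2) - f**2)
        assert m.robustness_value(3.0, 100, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_xrv_alpha_one_is_partial_r2(self):
        for t, df in [(3, 100), (10, 1000), (1.2, 37)]:
            assert m.extreme_robustness_value(t, df, 1.0) == m.partial_r2_from_t(t, df)

    def test_xrv_direct_arithmetic(self):
        t, df, alpha = 10.0, 1000, 0.05
        f2 = t * t / df
        fs2 = critical_t(alpha, df - 1) ** 2 / (df - 1)
        assert m.extreme_robustness_value(t, df, alpha) == pytest.approx(
            (f2 - fs2) / (1 + f2), rel=1e-12
        )

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            m.robustness_value(2.0, 100, 0.0)
        with pytest.raises(ValueError):
            m.extreme_robustness_value(2.0, 100, 1.5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    t1=st.floats(0.0, 30.0),
    dt=st.floats(0.01, 10.0),
    df=st.integers(10, 100_000),
    alpha=st.sampled_from([0.01, 0.05, 0.2, 1.0]),
)
def test_rv_and_xrv_monotone_in_t(t1, dt, df, alpha):
    """RV and XRV never decrease as |t| grows, at fixed df and alpha."""
    assert m.robustness_value(t1 + dt, df, alpha) >= m.robustness_value(t1, df, alpha)
    assert m.extreme_robustness_value(t1 + dt, df, alpha) >= m.extreme_robustness_value(
        t1, df, alpha
    )
    assert 0.0 <= m.robustness_value(t1, df, alpha) <= 1.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    rz=st.floats(0.0, 0.95),
    drz=st.floats(0.001, 0.05),
    rt=st.floats(0.0, 1.0),
)
def test_adjusted_t_monotone_in_instrument_strength(rz, drz, rt):
    """Toward-null adjusted t never grows with the instrument-side R²."""
    assoc = m.AssociationSummary(0.5, 0.1, 200)
    lo = m.adjusted_t(assoc, m.SensitivityParams(min(rz + drz, 0.999), rt))
    hi = m.adjusted_t(assoc, m.SensitivityParams(rz, rt))
    assert lo <= hi + 1e-9


@settings(max_examples=200, deadline=None, derandomize=True)
@given(rt=st.floats(0.0, 0.98), drt=st.floats(0.001, 0.02))
def test_adjusted_t_monotone_in_trait_strength_above_partial_r2(rt, drt):
    """On the instrument axis at/above the partial R², the toward-null
    adjusted t is nonincreasing in the trait-side R² (below the partial R²
    the zero contour has a vertical asymptote and monotonicity fails)."""
    assoc = m.AssociationSummary(0.5, 0.1, 200)
    rz = m.partial_r2_from_t(assoc.t_value, assoc.df)
    lo = m.adjusted_t(assoc, m.SensitivityParams(rz, min(rt + drt, 1.0)))
    hi = m.adjusted_t(assoc, m.SensitivityParams(rz, rt))
    assert lo <= hi + 1e-9


def test_rv_vanishes_at_significance_boundary():
    """As alpha approaches the observed p-value, RV tends to zero."""
    t, df = 2.5, 300
    assoc = m.AssociationSummary(t, 1.0, df)
    p_obs = assoc.p_value()
    rvs = [m.robustness_value(t, df, a) for a in (p_obs * 3, p_obs * 1.5, p_obs * 1.05)]
    assert rvs[0] > rvs[1] > rvs[2]
    assert rvs[2] < 5e-3
    assert m.robustness_value(t, df, p_obs * 0.5) == 0.0


def test_multivariate_w_formulas_are_conservative():
    """With a two-column W at its joint partial R² strengths, the true
    fully adjusted |t| is never below the formula's worst case."""
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = 150
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        z = rng.standard_normal(n)
        w = rng.standard_normal((n, 2)) + 0.3 * z[:, None]
        y = 0.6 * z + w @ rng.uniform(0.2, 0.8, 2) + rng.standard_normal(n)
        restricted = sm.OLS(y, np.column_stack([z, x])).fit()
        full = sm.OLS(y, np.column_stack([z, w, x])).fit()
        if abs(full.params[0]) >= abs(restricted.params[0]):
            continue  # conservative claim concerns bias toward the null

        def group_r2(target, exog_full, exog_reduced):
            rss_f = sm.OLS(target, exog_full).fit().ssr
            rss_r = sm.OLS(target, exog_reduced).fit().ssr
            return (rss_r - rss_f) / rss_r

        r2_wz = group_r2(z, np.column_stack([w, x]), x)
        r2_wt = group_r2(y, np.column_stack([z, w, x]), np.column_stack([z, x]))
        assoc = m.AssociationSummary(
            restricted.params[0], restricted.bse[0], int(restricted.df_resid)
        )
        sign = 1.0 if restricted.params[0] >= 0 else -1.0
        worst = sign * m.adjusted_t(assoc, m.SensitivityParams(r2_wz, r2_wt))
        # match df conventions: the formula spends one df on W, the real
        # two-column W spends two
        t_true = abs(full.tvalues[0]) * math.sqrt((assoc.df - 1) / full.df_resid)
        assert t_true >= worst - 1e-8


def test_sensitivity_stats_bundle_consistency():
    assoc = m.AssociationSummary(0.4, 0.05, 400)
    stats = m.sensitivity_stats(assoc, 0.05)
    assert stats.partial_r2 == pytest.approx(stats.f2 / (1 + stats.f2), rel=1e-12)
    assert stats.xrv_alpha <= stats.rv_alpha + 1e-12
    assert 0 <= stats.rv_alpha <= 1


def test_association_summary_validation():
    with pytest.raises(ValueError):
        m.AssociationSummary(1.0, 0.0, 100)
    with pytest.raises(ValueError):
        m.AssociationSummary(1.0, 0.1, 1)
    with pytest.raises(ValueError):
        m.AssociationSummary(1.0, 0.1, 100, t_value=5.0)
    ok = m.AssociationSummary(1.0, 0.1, 100)
    assert ok.t_value == pytest.approx(10.0)
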