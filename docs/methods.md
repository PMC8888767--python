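# Methods

## Model and estimand

We consider single-instrument MR on individual-level data: outcome trait
Y, exposure trait D, genetic instrument Z (usually a weighted genotype
score), observed covariates **X** (with an intercept), and unmeasured
variables **W** that would be needed to make Z a valid instrument. The
estimand is the instrumental-variable ratio τ = β_{YZ|XW} / β_{DZ|XW} of
the two partial regression coefficients of the traits on the instrument.
All algebra is exact finite-sample least-squares algebra
(Frisch–Waugh–Lovell residualization); no asymptotic approximation is
involved in the sensitivity formulas themselves, only in the usual
Student-t reference for test levels.

## Anderson–Rubin test and Fieller set

The AR test of H₀: τ = τ₀ is the t-test of the Z coefficient in the
regression of Y − τ₀·D on (Z, **X**). Writing β_Y = β_{YZ|X},
β_D = β_{DZ|X}, their estimated variances v_Y, v_D and covariance c (all
from the residualized cross-products divided by df = n − p − 1, p counting
covariate columns including the intercept), the test statistic is

    t(τ₀) = (β_Y − τ₀ β_D) / sqrt(v_Y + τ₀² v_D − 2 τ₀ c),

and the 1 − α confidence set is {τ₀ : a τ₀² + b τ₀ + c₀ ≤ 0} with
a = β_D² − v_D t*², b = 2(c t*² − β_Y β_D), c₀ = β_Y² − v_Y t*², where t*
is the two-sided Student-t critical value at df. Shapes: a > 0 gives a
bounded interval (the discriminant is then nonnegative because the
quadratic is nonpositive at the ratio point estimate — asserted, never an
empty set); a < 0 gives two unbounded rays (positive discriminant) or the
whole line. The measure-zero edge a = 0 is resolved as the linear
inequality b τ₀ + c₀ ≤ 0 and encoded as a degenerate ray. Two exact
equivalences drive the reporting flags: the set is unbounded iff
|t_{β_D}| ≤ t*, and contains zero iff |t_{β_Y}| ≤ t*. Coefficients, SEs
and the covariance are property-tested to reproduce classical
multivariable least-squares output exactly.

## Omitted-variable-bias adjustment

For a scalar W with instrument-side strength r_Z = R²_{ZW|X} and
trait-side strength r_T = R²_{TW|ZX}, the association adjusting for W is
recovered from the association adjusting for X alone:

    estimate' = estimate ∓ se · sqrt(r_T r_Z / (1 − r_Z) · df),
    se'       = se · sqrt((1 − r_T)/(1 − r_Z) · df/(df − 1)),

with the adjusted t referred to df − 1 (one degree of freedom spent on W).
The default direction is toward the null — the conservative question is
what removes a finding — and the estimate is allowed to cross zero so the
adjusted-t surface is continuous through full elimination. For
multivariate W the same formulas are the worst case (validated against
two-column W constructions, with the df convention matched).

A caution the algebra forces: the toward-null adjusted t is monotone
nonincreasing in r_Z everywhere, but along the trait axis only where
r_Z is at least the association's partial R²; below that threshold the
zero contour has a vertical asymptote and |t| eventually grows as
r_T → 1 (the residual variance shrinks faster than the bias grows). The
extreme robustness value is precisely the location of that asymptote. The
monotonicity test suite asserts the property on its true domain.

## Sensitivity statistics

With f = |t|/√df, f*_α = t*_{α,df−1}/√(df−1), f_α = f − f*_α:

* partial R² = t²/(t² + df) = f²/(1 + f²);
* RV_α = 0 if f_α < 0; ½(√(f_α⁴ + 4f_α²) − f_α²) if f*_α ≤ f < 1/f*_α;
  (f² − f*_α²)/(1 + f²) otherwise;
* XRV_α = 0 if f_α ≤ 0, else (f² − f*_α²)/(1 + f²), computed in the
  rearranged form (t² − df·f*_α²)/(t² + df) so that α = 1 reduces
  bit-for-bit to the partial R².

RV satisfies the fixed point |adjusted_t(RV, RV)| = t*_{α,df−1}, tested to
1e-6 and against an independent root-finder. Critical thresholds use
Student-t quantiles at df − 1 throughout; at biobank df the difference
from normal quantiles is negligible, but the t convention keeps the
small-sample algebra exact. Degenerate inputs: t = 0 gives RV = XRV = 0;
r_Z = 1 is rejected rather than mapped to infinity. All statistics are
proportions in [0, 1] internally; percent formatting happens only in
rendered tables and axes.

## Benchmark bounds and critical k

Relative claims ("W is at most k times as strong as the observed PCs")
are translated into strength bounds via the multipliers k_Z, k_Y of W's
partial R² relative to an observed covariate group Xj, for W orthogonal
to the observed covariates:

    R²_{ZW|X}  = k_Z · f²_{ZXj|X−j},
    R²_{TW|ZX} ≤ η² · f²_{TXj|X−j Z},   f² = R²/(1−R²),

with s = k_Z R²_{ZXj|X−j}² / ((1 − k_Z R²_{ZXj|X−j})(1 − R²_{ZXj|X−j}))
and η = (√k_Y + √s)/√(1 − s), the trait-side bound capped at 1. The η
form is validated purely through a conservativeness oracle: over many
synthetic datasets with a planted, in-sample-orthogonalized scalar W and
multipliers computed in-sample, the bound never understates W's true
partial R² pair (the instrument side is an identity, the trait side an
inequality — both hold to machine precision). Benchmark groups (e.g. "20
leading PCs") are treated jointly via nested-RSS partial R², one bound per
group, since that is the natural reporting unit.

Critical k sets k_Z = k_Y = k and finds the smallest k at which the
worst-case adjusted t at the bound point falls to t*_{α,df−1}: a coarse
scan over the feasible range [0, (1−ε)/f²_{ZXj|X−j}] locates the first
crossing (the adjusted t need not be globally monotone in k), then Brent
bisection refines it to 1e-6. Already-insignificant associations return
0; if no feasible multiple suffices (possible only when the benchmark has
zero instrument-side strength) the sentinel +∞ is returned with a log
note. Degrees of freedom at the bound point are df − 1 regardless of
benchmark group size, matching the scalar-W worst-case framing.

## Contour grids and reports

The default grid is 100×100 with each axis limit min(0.4, 20 × partial
R²) of the association displayed, adapting the window to the association
strength. Cells are the toward-null adjusted t; the critical contour t*
and the zero contour are drawn specially, benchmark bounds as diamonds,
the unadjusted association as the origin triangle. Every rendered plot
writes a delimited sidecar of the full grid so the figure is
re-derivable. The minimal report carries, per association: estimate, SE,
t, p, partial R², RV_α; plus the ratio estimate, the Fieller set with its
shape tag, the AR zero-null p-value, the bound table, and the two
decomposition flags (weak instrument ⇔ unbounded set; MR significance ⇔
outcome-association significance, asserted equal on every input).

## Simulation bench

The data-generating process routes weak pleiotropy through an observed
trait X and an unobserved trait W, both linear in the genotypes:

    W = Σ_j φ_j G_j + ε_W,  X = Σ_j δ_j G_j + ε_X,
    D = Σ_j β_j G_j + X + W + U + ε_D,
    Y = τ D + η X + γ W + U + ε_Y,

with G_j ~ Binom(2, 1/3) i.i.d., standard normal noise, J = 90 variants,
β_j, φ_j, δ_j ~ U(0.01, 0.05) and η = γ = 0.05 by default. Valid variants
have φ_j = δ_j = 0; the per-variant magnitudes of the invalid variants
are not redistributed when some variants are valid, so false-positive
rates decline monotonically as the valid count grows. Because φ, δ, β are
all positive, instrument strength correlates with the pleiotropic direct
effects (an InSIDE violation), and the pleiotropy mode is nonzero in any
finite sample.

Each replicate draws one set of effect vectors shared by two independent
cohorts of N individuals (the two-sample design: effects are population
parameters, samples are not). Per-variant marginal regressions in cohort
1 (exposure) and cohort 2 (outcome) feed IVW (weights 1/se_Y², slope
through the origin) and MR-Egger (same weights, with intercept), both
with multiplicative random-effects inflation floored at 1 and a normal
reference — the common default dialect of summary-statistic MR packages.
The sensitivity columns are computed on the score built in the outcome
cohort with exposure-cohort weights, regressed on Y controlling for the
observed X (the only observed benchmark the DGP provides); RV at
α = 0.05 from that association's t and df, and critical k against the
1×-X benchmark. Percentiles across replicates use linear interpolation.
Reproducibility comes from per-scenario, per-replicate seed-sequence
substreams: identical seeds give byte-identical results.

Genotypes are generated as a sum of two Bernoulli threshold draws written
directly into a float array; this is distributionally identical to a
binomial draw and avoids a large integer intermediate at biobank-scale N.

Problem sizes used by the shipped experiments: the headline scenario runs
N = 150,000 per cohort at 200 replicates (a few minutes on one CPU);
level and power checks in the test suite use smaller cohorts
(N = 500–100,000) with replicate counts sized so binomial Monte-Carlo
bands are informative.

## Synthetic fixtures: what they do and do not show

`generate_fixture` writes small self-contained datasets (phenotype table,
dosage matrix, score weights, JSON sidecar with the true τ and the
planted W strengths in closed form) for three canonical threats: a valid
instrument, an unmeasured confounder of instrument and outcome, and a
horizontal pleiotropic pathway sharing the instrument's variants. They
are linear-Gaussian with independent covariates and a handful of
variants: they exercise every code path and make the oracle algebra
checkable, but they do not emulate linkage disequilibrium, allele
frequency spectra, non-linear or interactive effects, selection, or
missing-data mechanisms of real biobank data. Passing tests certify the
algebra and the plumbing, not robustness to those real-data features.

## Numerical choices

* Collinear covariate columns are dropped deterministically
  (left-to-right scan, residual-norm tolerance 1e-9 relative) with a
  warning; rows with missing values among used columns are dropped with a
  logged count; missing dosages are mean-imputed per variant.
* Cauchy–Schwarz is enforced on the fitted coefficient covariance; a
  zero-residual-variance instrument raises a degenerate-instrument error.
* When the trait-side strength reaches 1 the adjusted SE is zero and the
  adjusted t is ±∞ by convention (0 when the estimate is also fully
  eliminated).
* Fieller endpoints come from the closed-form quadratic roots; the grid
  inversion in the tests is an independent check, not the implementation.

## Known limitations

Single-instrument analyses only (an overidentified multi-instrument AR
test is out of scope); linear homoscedastic regressions; bounds assume
the benchmark group is a reasonable proxy and W orthogonal to observed
covariates; the E-value parameterization and risk-ratio scales are not
provided; the comparison estimators implemented are IVW and MR-Egger —
outlier-removal and mode/mixture-based estimators are not reimplemented.
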