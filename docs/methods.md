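# Methods

## The probit liability threshold model

A binary trait (here: a cancer diagnosis over a lifetime) is modelled
through a latent liability `L ~ N(0, 1)` that decomposes into independent
genetic and residual parts, `L = L_G + L_E` with `L_G ~ N(0, h²)` and
`L_E ~ N(0, 1 − h²)`; `h²` is the heritability of liability.  An individual
is affected iff `L > t` with `t = Φ⁻¹(q)`, where `1 − q` is the lifetime
risk.  (For the continuous model `L ≥ t` and `L > t` coincide; the package
fixes the strict-inequality convention.)

Conditioning on the genetic liability `ι_G` gives the absolute genetic risk

    g(ι_G) = Φ((ι_G − t) / √(1 − h²)),

interpreted as the individual's lifetime risk were the genotype known but
the environment unknown.  Viewing `Y = g(L_G)` as a random variable yields
the population distribution of absolute genetic risk.  Its closed forms,
all implemented in `ginirisk.liability`:

* inverse map:   `g⁻¹(y) = Φ⁻¹(y)·√(1 − h²) + t`
* density:       `f_Y(y) = √((1−h²)/h²) · exp(−g⁻¹(y)²/(2h²) + Φ⁻¹(y)²/2)`
* cdf:           `F_Y(y) = Φ(g⁻¹(y)/√h²)`
* quantile:      `y_p = Φ((√h²·Φ⁻¹(p) − t)/√(1 − h²))`
* mean:          `E(Y) = 1 − q` exactly (law of total probability)

The density can diverge at either endpoint (for `h² > 1/2` both tails),
but the singularities are integrable.  All moment and tail integrals are
therefore evaluated after the change of variables `y = g(√h²·z)` with `z`
standard normal, i.e. as Gaussian-weighted integrals over the real line,
using adaptive quadrature (`scipy.integrate.quad`, absolute tolerance
1e-12; results whose reported error exceeds 1e-8 raise `QuadratureError`).
This also preserves full relative accuracy in the lower tail, which
matters because top/bottom-20% ratios span roughly 9 to 2·10⁵ across the
packaged traits.

Simulation follows the generative definition directly: draw
`L_G ~ N(0, h²)` with a seeded `numpy` generator and transform through
`g`.  Simulation is used as an independent cross-check of the quadrature
path, never as the primary computation.

Boundary conventions: `h² = 0` returns a degenerate point mass at the
lifetime risk (Gini 0, all quantiles equal to the mean); `h² = 1` and
lifetime risks of exactly 0 or 1 are rejected, since the density is
undefined there.  Arguments of `Φ⁻¹` are clipped to `[1e-15, 1 − 1e-15]`
with a logged warning; risks closer to the boundary than that are below
double-precision resolution.

## Inequality metrics

For any risk distribution on [0, 1] exposing mean, cdf and quantiles
(`ginirisk.inequality` works against that duck-typed surface):

* **Lorenz curve.**  `L(x) = (1/E(Y)) ∫₀ˣ t f_Y(t) dt` is the share of the
  total risk burden carried by individuals with risk at most `x`.  The
  population parameterisation `L(quantile(S))` — the share carried by the
  lowest-risk fraction `S` — is what is usually plotted; both are exposed
  and the docstrings state which is which.
* **Gini index.**  Defined as twice the pdf-weighted mean deviation between
  cdf and Lorenz curve, equivalently half the relative mean absolute
  difference.  Computed in quantile space as `G = (2/μ)·∫₀¹ p·Q(p) dp − 1`,
  which equals one minus twice the area under the population Lorenz curve
  (integration by parts) but needs only a single quadrature of a bounded,
  smooth integrand built from the closed-form quantile function.  The
  equivalence with the Lorenz-area form and, for beta variables, with the
  closed form `G = 2B(2α,2β)/(α·B(α,β)²)` is asserted in the test suite to
  1e-6 or better.
* **Quantile ratio.**  `RR_p:p` is the ratio of the mean risk in the top
  `p` tail to the bottom `p` tail (the equal masses `p` cancel); `p = 0.2`
  gives the 20:20 ratio used in economics.
* **Intervention relative risk.**  Capping every risk above the `1−p`
  quantile at the mean of the bottom `p` tail gives
  `RR_interv = (∫₀^{y_{1−p}} y f dy + ∫₀^{y_p} y f dy) / E(Y)`, the
  relative case count after the hypothetical intervention; `1 − RR_interv`
  is the proportional case reduction.

Degenerate (equal-risk) distributions use the conventions Gini = 0 and
both ratios = 1.  A bottom tail that underflows to zero mass reports the
quantile ratio as `+inf` with a warning rather than raising.

A sorted-sample mean-absolute-difference estimator (`gini_mc_oracle`)
provides the Monte-Carlo route used in the equivalence tests.

## The beta model from twin recurrence

The heritability-free alternative assumes each individual carries a fixed
risk `p_i` shared exactly by monozygotic (MZ) co-twins, so `p_i` captures
genes and shared family environment jointly.  The MZ recurrence risk ratio
then satisfies `λ_M = 1 + VAR(p_i)/E(p_i)²`, giving
`VAR(p_i) = (λ_M − 1)·I_life²` with `E(p_i) = I_life` the lifetime risk.
A beta distribution is fitted to those two moments (standard method of
moments; feasibility requires `VAR < I(1−I)`, i.e. `λ_M < 1/I_life`, and
the error message reports that bound).  Its Gini index has the closed form
above.  `λ_M = 1` is a valid limiting case and returns the degenerate
distribution rather than an error.

Because `p_i` absorbs shared environment as well as genes, beta-model
inequality estimates are upper bounds relative to the heritability-only
probit estimates; on the packaged table every trait with a positive
shared-environment component indeed has `GC_beta ≥ GC_h²` (kept as a
regression test, not claimed as a theorem).

The same `(λ_M, I_life)` pair can instead parameterise the probit family:
`solve_h_env2` finds the shape `h²_env ∈ (0,1)` — now the liability
variance fraction due to genes *plus* shared environment, not a
heritability — such that `E(Y²) = λ_M·E(Y)²`.  The residual is continuous
and monotone in the shape on all tested grids, so bracketed Brent root
finding on `[1e-6, 1−1e-6]` (tolerance 1e-8) is used; absence of a sign
change raises a feasibility error.

## The packaged table and its reproduction

`ginirisk/data/nordic_twin_cancers.tsv` stores the published inputs for
15 cancer sites plus overall cancer from the Nordic twin registry study
(Mucci et al., JAMA 2016): heritability `h²`, shared-environment fraction
`env²` and lifetime risk in percent exactly as printed (1 decimal), and
`λ_M` as a ratio (1 decimal).  Percent-to-fraction conversion happens in a
single guarded function at the API boundary.  `reproduce_table` derives,
per trait, the probit Gini, the beta Gini, the 20:20 ratio and the
intervention RR, optionally rounded half-up to the published precision
(2 decimals for Gini and RR_interv, nearest integer for the 20:20 ratio);
unrounded values are retained by default and two runs are byte-identical
(the quadrature path has no randomness).

Confidence bounds for `h²` and `λ_M` are not part of the packaged fixture
(the source confidence intervals are not reprinted in the inputs shipped
here); `propagate_bounds` implements the plug-in scheme — re-evaluate a
metric at the parameter's lower and upper confidence limits with the
lifetime risk fixed — and is exercised with synthetic bounds in the tests.
Monotonicity of the metric in the parameter is checked, not assumed: if
the metric decreases (as the intervention RR does in `h²`), the interval
is reordered with a logged warning.  Records without bounds raise an
explicit "no CI available" error rather than returning zeros.

### Input-rounding sensitivity

The published derived columns were evidently computed from unrounded
source estimates, while the reprinted inputs carry one decimal.  For most
traits this is invisible at the printed precision; the documented
exceptions are driven by `λ_M`: for overall cancer, `λ_M = 1.4` yields a
beta Gini of 0.358 versus the printed 0.37, which is recovered at
`λ_M ≈ 1.43` — consistent with the probit-implied recurrence ratio 1.426
at `h² = 0.33`.  The test suite therefore pins the four beta-Gini spot
values that are insensitive to this rounding at ±0.01 and asserts, for
every trait, that the printed value lies inside the band swept by
`λ_M ± 0.05` (the printing precision) widened by the ±0.01 rounding of the
Gini column itself.  Extreme 20:20 ratios (melanoma, leukemia) are
similarly sensitive to 1-dp inputs, hence the relative (10%) tolerance on
the quantile-ratio check.

## What the tests do and do not show

The dual verification strategy — every quadrature quantity also computed
by seeded 10⁶-draw simulation (3 Monte-Carlo-SE agreement for mean,
variance and Gini on all 16 traits), second moments checked against the
bivariate-normal MZ-concordance orthant probability via Owen's T function,
beta Ginis checked against closed forms — validates the numerics of the
model, not the model itself.  The probit and beta families are modelling
assumptions: liability normality is untestable with summary data,
gene-environment independence on the liability scale is assumed, and the
inputs are point estimates from one set of Nordic twin cohorts.
Reproducing the published columns shows the machinery is faithful; it does
not generalise the risk distributions beyond the populations and
assumptions behind the input estimates.

## Problem sizes and tolerances

Quadrature: adaptive, absolute tolerance 1e-12, error threshold 1e-8.
Closed-form identities (inverse maps, cdf∘quantile) hold to 1e-10.
Simulation checks use 10⁶ draws per trait with seeds derived from the
trait's table index; the whole suite runs in under two minutes on one
core.  Brent tolerance for the shape solver is 1e-8 on the shape, giving
recurrence-ratio roundtrips well inside 1e-6.
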