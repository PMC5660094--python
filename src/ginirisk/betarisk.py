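"""Heritability-free risk model from twin recurrence: the beta family.

Instead of decomposing liability variance, this model assumes each person
carries a fixed probability of disease p_i drawn from a beta distribution
and shared exactly by monozygotic (MZ) co-twins, so p_i captures genes and
shared family environment jointly.  Under that assumption the MZ recurrence
risk ratio satisfies

    lambda_M = 1 + VAR(p_i) / E(p_i)^2,

so (lambda_M, lifetime risk) pins down both beta moments and hence, by
moment matching, the whole distribution.  Its Gini index has the closed
form G = 2 B(2a, 2b) / (a B(a, b)^2) with B the beta function.

The same pair can alternatively parameterise the probit risk distribution:
``solve_h_env2`` finds the shape h_env2 (liability variance fraction due to
genes plus shared environment) whose implied recurrence ratio matches the
observed lambda_M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .exceptions import FeasibilityError, ParameterDomainError
from .liability import (
    DegenerateRiskDistribution,
    LiabilityModelParams,
    ProbitRiskDistribution,
)


@dataclass(frozen=True)
class BetaTwinInputs:
    """Observed summaries driving the beta model.

    Parameters
    ----------
    lambda_m : float
        MZ twin recurrence risk ratio, >= 1.
    lifetime_risk : float
        Lifetime probability of disease I_life, in (0, 1).
    """

    lambda_m: float
    lifetime_risk: float

    def __post_init__(self) -> None:
        if self.lambda_m < 1.0:
            raise ParameterDomainError(
                f"lambda_m must be >= 1, got {self.lambda_m!r}"
            )
        if not (0.0 < self.lifetime_risk < 1.0):
            raise ParameterDomainError(
                f"lifetime_risk must lie in (0, 1), got {self.lifetime_risk!r}"
            )


def moments_from_twin_recurrence(inputs: BetaTwinInputs) -> tuple[float, float]:
    """Mean and variance of individual risk implied by (lambda_M, I_life).

    mean = I_life and VAR = (lambda_M - 1) I_life^2, from the recurrence
    identity for co-twins sharing the risk value.
    """
    mean = inputs.lifetime_risk
    variance = (inputs.lambda_m - 1.0) * mean**2
    return mean, variance


def lambda_from_moments(mean: float, variance: float) -> float:
    """Recurrence ratio 1 + VAR/mean^2 implied by risk moments."""
    if not (0.0 < mean < 1.0):
        raise ParameterDomainError(f"mean risk must lie in (0, 1), got {mean!r}")
    if variance < 0.0:
        raise ParameterDomainError(f"variance must be >= 0, got {variance!r}")
    return 1.0 + variance / mean**2


class BetaRiskDistribution:
    """Beta(alpha, beta) distribution of individual absolute risk.

    Thin wrapper over ``scipy.stats.beta`` exposing the same surface as
    :class:`~ginirisk.liability.ProbitRiskDistribution` (pdf, cdf, quantile,
    mean, variance, partial_mean, sample).
    """

    def __init__(self, alpha: float, beta_shape: float):
        if alpha <= 0.0 or beta_shape <= 0.0:
            raise ParameterDomainError(
                f"beta shapes must be > 0, got ({alpha!r}, {beta_shape!r})"
            )
        self.alpha = float(alpha)
        self.beta_shape = float(beta_shape)
        self._frozen = stats.beta(self.alpha, self.beta_shape)

    def pdf(self, y):
        return self._frozen.pdf(y)

    def cdf(self, y):
        return self._frozen.cdf(y)

    def quantile(self, prob):
        prob = np.asarray(prob, dtype=float)
        if np.any(prob <= 0.0) or np.any(prob >= 1.0):
            raise ParameterDomainError("quantile defined for p in (0, 1)")
        out = self._frozen.ppf(prob)
        return float(out) if np.ndim(out) == 0 else out

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta_shape)

    def variance(self) -> float:
        return float(self._frozen.var())

    def partial_mean(self, x) -> float:
        """Lower partial expectation via the regularised incomplete beta.

        ``int_0^x y f(y) dy = mean * I_x(alpha + 1, beta)``.
        """
        x = float(x)
        if not (0.0 <= x <= 1.0):
            raise ParameterDomainError("partial_mean defined on [0, 1]")
        return self.mean * float(special.betainc(self.alpha + 1.0, self.beta_shape, x))

    def sample(self, n: int, seed=None) -> np.ndarray:
        if n < 1:
            raise ValueError(f"sample size must be >= 1, got {n}")
        rng = np.random.default_rng(seed)
        return self._frozen.rvs(size=int(n), random_state=rng)


def beta_from_moments(mean: float, variance: float) -> BetaRiskDistribution:
    """Moment-matched Beta(alpha, beta) with the given mean and variance.

    alpha = mean * k and beta = (1 - mean) * k with
    k = mean (1 - mean) / variance - 1.  The variance must satisfy
    0 < variance < mean (1 - mean) for a proper beta distribution.
    """
    if not (0.0 < mean < 1.0):
        raise ParameterDomainError(f"mean must lie in (0, 1), got {mean!r}")
    bound = mean * (1.0 - mean)
    if not (0.0 < variance < bound):
        raise FeasibilityError(
            f"variance {variance!r} infeasible for a beta distribution with "
            f"mean {mean!r}: must lie strictly inside (0, {bound:.6g})"
        )
    k = bound / variance - 1.0
    return BetaRiskDistribution(alpha=mean * k, beta_shape=(1.0 - mean) * k)


def beta_risk_from_twin_data(inputs: BetaTwinInputs):
    """Risk distribution for (lambda_M, I_life); degenerate if lambda_M = 1.

    For lambda_M > 1 the implied variance must respect the beta bound
    VAR < I(1 - I); otherwise the error reports the maximum admissible
    lambda_M (= 1/I_life) for the given lifetime risk.
    """
    mean, variance = moments_from_twin_recurrence(inputs)
    if variance == 0.0:
        return DegenerateRiskDistribution(mean)
    if variance >= mean * (1.0 - mean):
        raise FeasibilityError(
            f"lambda_m = {inputs.lambda_m} infeasible for lifetime risk "
            f"{mean}: the beta model requires lambda_m < {1.0 / mean:.6g}"
        )
    return beta_from_moments(mean, variance)


def gini_beta(dist: BetaRiskDistribution) -> float:
    """Closed-form Gini index 2 B(2a, 2b) / (a B(a, b)^2) of a beta variable.

    Evaluated through log-beta functions to stay finite for small shapes.
    """
    a, b = dist.alpha, dist.beta_shape
    if a <= 0.0 or b <= 0.0:
        raise ParameterDomainError("beta shapes must be > 0")
    return float(
        2.0 * np.exp(special.betaln(2.0 * a, 2.0 * b) - 2.0 * special.betaln(a, b)) / a
    )


@dataclass(frozen=True)
class ProbitShapeFit:
    """Solution of the probit shape parameter matched to a recurrence ratio.

    ``h_env2`` is the fraction of liability variance due to genes plus
    shared environment — a shape parameter, not a heritability.
    """

    h_env2: float
    residual: float
    iterations: int

    def distribution(self, lifetime_risk: float):
        """Probit risk distribution with shape h_env2 at the given lifetime risk."""
        if self.h_env2 == 0.0:
            return DegenerateRiskDistribution(lifetime_risk)
        return ProbitRiskDistribution(
            LiabilityModelParams(h2=self.h_env2, lifetime_risk=lifetime_risk)
        )


def solve_h_env2(
    inputs: BetaTwinInputs,
    tol: float = 1e-8,
    bracket: tuple[float, float] = (1e-6, 1.0 - 1e-6),
) -> ProbitShapeFit:
    """Solve for the probit shape whose implied recurrence ratio is lambda_M.

    Finds h_env2 in (0, 1) such that the probit risk distribution with that
    shape satisfies E(Y^2) = lambda_M * E(Y)^2, i.e. the residual

        (lambda_M - 1) (1-q)^2 - E(Y^2) + (1-q)^2

    vanishes.  The residual is monotone in the shape on tested grids, so a
    bracketed Brent search is used.  lambda_M = 1 returns the degenerate
    equal-risk fit directly.
    """
    mu = inputs.lifetime_risk
    if inputs.lambda_m == 1.0:
        return ProbitShapeFit(h_env2=0.0, residual=0.0, iterations=0)
    target = inputs.lambda_m * mu**2  # required E(Y^2)

    def residual(h2: float) -> float:
        dist = ProbitRiskDistribution(
            LiabilityModelParams(h2=h2, lifetime_risk=mu)
        )
        return target - dist.moment(2)

    lo, hi = bracket
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0.0:
        raise FeasibilityError(
            f"no probit shape in [{lo:.2g}, {hi:.2g}] matches lambda_m = "
            f"{inputs.lambda_m} at lifetime risk {mu} "
            f"(residuals {f_lo:.3e}, {f_hi:.3e} do not bracket a root)"
        )
    root, info = optimize.brentq(
        residual, lo, hi, xtol=tol, rtol=4 * np.finfo(float).eps, full_output=True
    )
    if not info.converged:
        raise ArithmeticError(
            f"Brent search for h_env2 did not converge: {info.flag}"
        )
    return ProbitShapeFit(
        h_env2=float(root),
        residual=float(residual(float(root))),
        iterations=int(info.iterations),
    )
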