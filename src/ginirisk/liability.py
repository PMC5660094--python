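"""Probit liability threshold model and the induced absolute-risk distribution.

The liability threshold model posits a latent liability L ~ N(0, 1) that is
the sum of a genetic component L_G ~ N(0, h2) and an independent residual
with variance 1 - h2.  An individual is affected iff L exceeds the threshold
t = Phi^{-1}(q), where 1 - q is the lifetime risk of the trait.  Conditioning
on the genetic liability iota_G gives the absolute genetic risk

    g(iota_G) = Phi((iota_G - t) / sqrt(1 - h2)),

and viewing Y = g(L_G) as a random variable yields the population
distribution of absolute risk due to genetic differences.  This module
exposes that distribution analytically (pdf, cdf, quantile, moments) and by
seeded simulation.

All moment integrals are evaluated on the liability scale: substituting
y = g(sqrt(h2) * z) with z standard normal turns every integral over the
risk support (0, 1) into a Gaussian-weighted integral over the real line,
which avoids the integrable endpoint singularities of the risk-scale
density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import norm

from .exceptions import ParameterDomainError, QuadratureError

logger = logging.getLogger(__name__)

#: Clipping bound for arguments of the normal quantile function.  Risks
#: closer than this to 0 or 1 underflow in double precision.
PPF_CLIP_EPS = 1e-15

#: Absolute tolerance requested from adaptive quadrature.
QUAD_ABS_TOL = 1e-12

#: A quadrature result whose reported error exceeds this is rejected.
QUAD_MAX_ERR = 1e-8


def _clipped_ppf(p):
    """Normal quantile with arguments clipped to [eps, 1 - eps].

    Clipping is logged because it signals risks beyond double-precision
    resolution rather than a silent numerical fix.
    """
    p = np.asarray(p, dtype=float)
    clipped = np.clip(p, PPF_CLIP_EPS, 1.0 - PPF_CLIP_EPS)
    if np.any(clipped != p):
        logger.warning(
            "normal quantile argument clipped to [%g, %g]",
            PPF_CLIP_EPS,
            1.0 - PPF_CLIP_EPS,
        )
    return norm.ppf(clipped)


@dataclass(frozen=True)
class LiabilityModelParams:
    """Parameters of the liability threshold model for one trait.

    Parameters
    ----------
    h2 : float
        Fraction of liability variance attributable to the genetic
        component (heritability of liability), in [0, 1).  The total
        liability variance is fixed at 1, so the residual variance is
        1 - h2.  ``h2 == 0`` is admitted as the degenerate equal-risk
        limit; ``h2 == 1`` is rejected because the risk density is
        undefined there.
    lifetime_risk : float
        Lifetime probability of being affected, in (0, 1).  Equals 1 - q,
        where q fixes the liability threshold ``Phi^{-1}(q)``.
    """

    h2: float
    lifetime_risk: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 < 1.0):
            raise ParameterDomainError(
                f"h2 must lie in [0, 1), got {self.h2!r}"
            )
        if not (0.0 < self.lifetime_risk < 1.0):
            raise ParameterDomainError(
                f"lifetime_risk must lie in (0, 1), got {self.lifetime_risk!r}"
            )

    @property
    def q(self) -> float:
        """Probability of remaining unaffected, 1 - lifetime_risk."""
        return 1.0 - self.lifetime_risk

    @property
    def threshold(self) -> float:
        """Liability threshold Phi^{-1}(q): affected iff L > threshold."""
        return float(norm.ppf(self.q))

    @property
    def genetic_sd(self) -> float:
        """Standard deviation sqrt(h2) of the genetic liability."""
        return math.sqrt(self.h2)

    @property
    def residual_sd(self) -> float:
        """Standard deviation sqrt(1 - h2) of the non-genetic liability."""
        return math.sqrt(1.0 - self.h2)


def risk_given_genetic_liability(iota_g, params: LiabilityModelParams):
    """Absolute risk g(iota_G) of disease given the genetic liability.

    Implements the probit transform
    ``g(iota_G) = Phi((iota_G - Phi^{-1}(q)) / sqrt(1 - h2))``,
    strictly increasing in ``iota_g`` with values in (0, 1).
    """
    iota_g = np.asarray(iota_g, dtype=float)
    out = norm.cdf((iota_g - params.threshold) / params.residual_sd)
    return float(out) if out.ndim == 0 else out


def genetic_liability_given_risk(y, params: LiabilityModelParams):
    """Genetic liability producing risk ``y``; inverse of the probit map.

    ``g^{-1}(y) = Phi^{-1}(y) sqrt(1 - h2) + Phi^{-1}(q)`` for y in the
    open interval (0, 1).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ParameterDomainError("risk must lie strictly inside (0, 1)")
    out = _clipped_ppf(y) * params.residual_sd + params.threshold
    return float(out) if out.ndim == 0 else out


def _checked_quad(fun, a, b, what: str) -> float:
    value, err = integrate.quad(
        fun, a, b, epsabs=QUAD_ABS_TOL, epsrel=1e-10, limit=200
    )
    if err > QUAD_MAX_ERR:
        raise QuadratureError(
            f"{what}: quadrature error estimate {err:.3e} exceeds "
            f"{QUAD_MAX_ERR:.0e} on [{a}, {b}]"
        )
    return value


class ProbitRiskDistribution:
    """Distribution of absolute genetic risk Y = g(L_G) under the probit model.

    Exposes the closed-form density, distribution function and quantiles,
    moment integrals by adaptive Gaussian-weighted quadrature, and the
    forward simulation (draw L_G ~ N(0, h2), transform through g).

    For ``h2 == 0`` use :func:`probit_risk_distribution`, which returns the
    degenerate point mass at the lifetime risk instead.
    """

    def __init__(self, params: LiabilityModelParams):
        if params.h2 <= 0.0:
            raise ParameterDomainError(
                "ProbitRiskDistribution requires h2 > 0; "
                "use probit_risk_distribution() for the degenerate limit"
            )
        self.params = params

    # -- conditional-risk map ------------------------------------------------

    def _g_std(self, z):
        """Risk as a function of the standardised genetic liability z = L_G/sqrt(h2)."""
        p = self.params
        return norm.cdf((p.genetic_sd * z - p.threshold) / p.residual_sd)

    # -- distribution functions ----------------------------------------------

    def pdf(self, y):
        """Density f_Y(y) of the absolute genetic risk, y in (0, 1).

        f_Y(y) = sqrt((1-h2)/h2) * exp(-(Phi^{-1}(y) sqrt(1-h2) + Phi^{-1}(q))^2
        / (2 h2) + Phi^{-1}(y)^2 / 2).  The density may diverge at the
        endpoints; the singularities are integrable.
        """
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0.0) or np.any(y >= 1.0):
            raise ParameterDomainError("pdf defined on the open interval (0, 1)")
        p = self.params
        z = _clipped_ppf(y)
        out = (p.residual_sd / p.genetic_sd) * np.exp(
            -((z * p.residual_sd + p.threshold) ** 2) / (2.0 * p.h2)
            + z**2 / 2.0
        )
        return float(out) if out.ndim == 0 else out

    def cdf(self, y):
        """Distribution function F_Y(y) = Phi(g^{-1}(y) / sqrt(h2))."""
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0.0) or np.any(y >= 1.0):
            raise ParameterDomainError("cdf defined on the open interval (0, 1)")
        p = self.params
        out = norm.cdf(genetic_liability_given_risk(y, p) / p.genetic_sd)
        return float(out) if np.ndim(out) == 0 else out

    def quantile(self, prob):
        """Quantile y_p = Phi((sqrt(h2) Phi^{-1}(p) - Phi^{-1}(q)) / sqrt(1-h2))."""
        prob = np.asarray(prob, dtype=float)
        if np.any(prob <= 0.0) or np.any(prob >= 1.0):
            raise ParameterDomainError("quantile defined for p in (0, 1)")
        p = self.params
        out = norm.cdf(
            (p.genetic_sd * norm.ppf(prob) - p.threshold) / p.residual_sd
        )
        return float(out) if out.ndim == 0 else out

    # -- moments ---------------------------------------------------------------

    @property
    def mean(self) -> float:
        """E(Y) = lifetime risk, exactly (law of total probability)."""
        return self.params.lifetime_risk

    def moment(self, order: int) -> float:
        """Raw moment E(Y^k) by Gaussian-weighted quadrature on the liability scale."""
        return _checked_quad(
            lambda z: norm.pdf(z) * self._g_std(z) ** order,
            -np.inf,
            np.inf,
            f"E(Y^{order})",
        )

    def variance(self) -> float:
        """VAR(Y) = E(Y^2) - E(Y)^2."""
        return self.moment(2) - self.mean**2

    def implied_lambda(self) -> float:
        """MZ twin recurrence risk ratio implied by this distribution.

        Equals 1 + VAR(Y)/E(Y)^2 = E(Y^2)/E(Y)^2, the recurrence ratio of
        co-twins sharing the genetic risk value.
        """
        return self.moment(2) / self.mean**2

    def partial_mean(self, x) -> float:
        """Lower partial expectation ``int_0^x y f_Y(y) dy`` for x in [0, 1].

        Computed as a truncated Gaussian-weighted integral on the liability
        scale, which keeps full relative accuracy deep in the lower tail
        (needed for extreme quantile ratios).
        """
        x = float(x)
        if not (0.0 <= x <= 1.0):
            raise ParameterDomainError("partial_mean defined on [0, 1]")
        if x == 0.0:
            return 0.0
        p = self.params
        if x == 1.0:
            upper = np.inf
        else:
            upper = genetic_liability_given_risk(x, p) / p.genetic_sd
        return _checked_quad(
            lambda z: norm.pdf(z) * self._g_std(z),
            -np.inf,
            upper,
            "partial mean",
        )

    # -- simulation --------------------------------------------------------------

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` absolute risks by forward simulation.

        Each draw takes a genetic liability L_G ~ N(0, h2) and transforms it
        through the probit risk map.  ``seed`` may be an integer or a
        ``numpy.random.Generator``; the same seed reproduces the same draws.
        """
        if n < 1:
            raise ValueError(f"sample size must be >= 1, got {n}")
        rng = np.random.default_rng(seed)
        p = self.params
        iota = rng.normal(0.0, p.genetic_sd, size=int(n))
        return risk_given_genetic_liability(iota, p)


class DegenerateRiskDistribution:
    """Point mass at a fixed risk: the equal-risk (h2 = 0, lambda_M = 1) limit.

    Every individual carries the same absolute risk, so the Gini index is 0
    and all quantiles coincide with the mean.
    """

    def __init__(self, risk: float):
        if not (0.0 < risk < 1.0):
            raise ParameterDomainError("degenerate risk must lie in (0, 1)")
        self.risk = float(risk)

    @property
    def mean(self) -> float:
        return self.risk

    def variance(self) -> float:
        return 0.0

    def cdf(self, y):
        y = np.asarray(y, dtype=float)
        out = np.where(y >= self.risk, 1.0, 0.0)
        return float(out) if out.ndim == 0 else out

    def quantile(self, prob):
        prob = np.asarray(prob, dtype=float)
        if np.any(prob <= 0.0) or np.any(prob >= 1.0):
            raise ParameterDomainError("quantile defined for p in (0, 1)")
        out = np.full_like(prob, self.risk, dtype=float)
        return float(out) if out.ndim == 0 else out

    def partial_mean(self, x) -> float:
        x = float(x)
        if not (0.0 <= x <= 1.0):
            raise ParameterDomainError("partial_mean defined on [0, 1]")
        return self.risk if x >= self.risk else 0.0

    def sample(self, n: int, seed=None) -> np.ndarray:
        if n < 1:
            raise ValueError(f"sample size must be >= 1, got {n}")
        return np.full(int(n), self.risk)


def probit_risk_distribution(h2: float, lifetime_risk: float):
    """Build the risk distribution for (h2, lifetime risk).

    Returns a :class:`ProbitRiskDistribution` for 0 < h2 < 1 and the
    degenerate point mass at the lifetime risk for h2 = 0.
    """
    params = LiabilityModelParams(h2=h2, lifetime_risk=lifetime_risk)
    if params.h2 == 0.0:
        return DegenerateRiskDistribution(lifetime_risk)
    return ProbitRiskDistribution(params)


def density_grid(dist, n: int = 512) -> np.ndarray:
    """Tabulate (y, f_Y(y)) on an interior grid, e.g. for plotting or export.

    The grid is placed at equally spaced population quantiles so that mass
    concentrations are resolved even for very skewed risk distributions.
    """
    probs = np.linspace(0.5 / n, 1.0 - 0.5 / n, n)
    y = dist.quantile(probs)
    return np.column_stack([y, dist.pdf(y)])
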