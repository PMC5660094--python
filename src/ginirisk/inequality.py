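"""Inequality metrics for absolute-risk distributions on [0, 1].

Works with any distribution object exposing ``mean``, ``variance()``,
``cdf``, ``quantile`` and ``sample`` (both the probit and the beta risk
distributions here do), plus an optional ``partial_mean(x)`` giving
``int_0^x y f(y) dy`` in closed or quadrature-stable form.

Two Lorenz parameterisations are exposed:

* :func:`lorenz` — L(x), the share of total risk carried by individuals
  whose risk is at most the value x (argument on the risk support);
* :func:`lorenz_population` — L(quantile(S)), the share carried by the
  lowest-risk fraction S of the population (the curve usually plotted).

The Gini index is computed from the population-share curve,
G = 1 - 2 * int_0^1 L(quantile(S)) dS, which is equivalent to the
pdf-weighted deviation integral 2 * int (F_Y - L) f_Y dy and to half the
relative mean absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .exceptions import ParameterDomainError, QuadratureError

_DEGENERATE_VAR = 1e-300  # variance at or below this is treated as a point mass


def _partial_mean(dist, x: float) -> float:
    """int_0^x y f(y) dy, preferring the distribution's own stable routine."""
    pm = getattr(dist, "partial_mean", None)
    if pm is not None:
        return pm(x)
    if not (0.0 <= x <= 1.0):
        raise ParameterDomainError("partial mean defined on [0, 1]")
    if x == 0.0:
        return 0.0
    value, err = integrate.quad(
        lambda t: t * dist.pdf(t), 0.0, x, epsabs=1e-12, epsrel=1e-10, limit=200
    )
    if err > 1e-8:
        raise QuadratureError(
            f"partial-mean quadrature error {err:.3e} too large at x={x}"
        )
    return value


def _is_degenerate(dist) -> bool:
    return dist.variance() <= _DEGENERATE_VAR


def lorenz(dist, x) -> float:
    """Cumulative share of total risk carried below the risk value ``x``.

    L(x) = (1/E(Y)) int_0^x t f(t) dt for x in [0, 1]; L(0) = 0, L(1) = 1.
    """
    x = float(x)
    if not (0.0 <= x <= 1.0):
        raise ParameterDomainError("lorenz defined for x in [0, 1]")
    return _partial_mean(dist, x) / dist.mean


def lorenz_population(dist, share) -> float:
    """Share of total risk carried by the lowest-risk fraction ``share``.

    This is the Lorenz curve in its population parameterisation,
    L(quantile(S)); under perfect equality it is the diagonal S.
    """
    share = float(share)
    if not (0.0 <= share <= 1.0):
        raise ParameterDomainError("population share must lie in [0, 1]")
    if share in (0.0, 1.0):
        return share
    if _is_degenerate(dist):
        return share
    return lorenz(dist, dist.quantile(share))


def gini(dist) -> float:
    """Gini index of a risk distribution, in [0, 1].

    0 means everyone carries the same risk; values near 1 mean the disease
    burden is concentrated in a small fraction of the population.  Computed
    in quantile space as G = (2/E(Y)) * int_0^1 p Q(p) dp - 1, which equals
    1 - 2 * (area under the population Lorenz curve) by integration by
    parts but needs only the closed-form quantile function; a degenerate
    distribution returns exactly 0.
    """
    if _is_degenerate(dist):
        return 0.0
    moment, err = integrate.quad(
        lambda p: p * dist.quantile(p),
        0.0,
        1.0,
        epsabs=1e-13,
        epsrel=1e-11,
        limit=200,
    )
    if err > 1e-8:
        raise QuadratureError(f"Gini quadrature error {err:.3e} too large")
    return 2.0 * moment / dist.mean - 1.0


def gini_mc_oracle(dist, n: int, seed=None) -> float:
    """Monte-Carlo Gini estimate from ``n`` seeded draws.

    Uses the sorted-sample form of the pairwise mean-absolute-difference
    estimator, G = sum_i (2i - n - 1) y_(i) / (n (n-1) mean), which is
    consistent for :func:`gini`.  Intended as an independent simulation
    cross-check of the quadrature path.
    """
    if n < 2:
        raise ValueError(f"need at least 2 draws, got {n}")
    y = np.sort(np.asarray(dist.sample(n, seed=seed), dtype=float))
    i = np.arange(1, n + 1)
    total = y.sum()
    if total == 0.0:
        return 0.0
    num = np.sum((2.0 * i - n - 1.0) * y)
    # the estimator is nonnegative up to rounding; floor tiny negatives
    return float(max(0.0, num / ((n - 1.0) * total)))


def quantile_ratio(dist, p: float = 0.2) -> float:
    """Ratio of mean risk in the top-p tail to the bottom-p tail.

    With y_p the lower p-quantile, the ratio is
    (E(Y) - int_0^{y_{1-p}} y f dy) / int_0^{y_p} y f dy; the equal
    population masses p cancel.  The conventional 20:20 ratio is p = 0.2.
    A degenerate distribution returns 1; a numerically zero bottom tail
    returns +inf.
    """
    if not (0.0 < p < 0.5):
        raise ParameterDomainError("tail fraction p must lie in (0, 0.5)")
    if _is_degenerate(dist):
        return 1.0
    bottom = _partial_mean(dist, dist.quantile(p))
    top = dist.mean - _partial_mean(dist, dist.quantile(1.0 - p))
    if bottom <= 0.0:
        import warnings

        warnings.warn(
            "bottom-tail risk mass underflowed to 0; quantile ratio reported "
            "as infinity",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return top / bottom


def intervention_rr(dist, p: float = 0.2) -> float:
    """Relative risk after capping the top-p tail at the bottom-p mean risk.

    Models an intervention that reduces every risk above the (1-p) quantile
    to the average risk of the lowest p of the population:

        RR = (int_0^{y_{1-p}} y f dy + int_0^{y_p} y f dy) / E(Y).

    Equals 1 only for a degenerate (equal-risk) distribution.
    """
    if not (0.0 < p < 0.5):
        raise ParameterDomainError("tail fraction p must lie in (0, 0.5)")
    if _is_degenerate(dist):
        return 1.0
    kept = _partial_mean(dist, dist.quantile(1.0 - p))
    replacement = _partial_mean(dist, dist.quantile(p))
    return (kept + replacement) / dist.mean


@dataclass(frozen=True)
class InequalitySummary:
    """Bundle of inequality metrics for one risk distribution.

    ``rr_quantile`` is the top-versus-bottom tail ratio at tail fraction
    ``p``; ``rr_intervention`` the post-intervention relative risk.  The
    optional bounds are plug-in values obtained by re-evaluating the metric
    at parameter confidence limits.
    """

    gini: float
    rr_quantile: float
    rr_intervention: float
    p: float = 0.2
    gini_lower: float | None = None
    gini_upper: float | None = None


def summarize(dist, p: float = 0.2) -> InequalitySummary:
    """Compute Gini, quantile ratio and intervention RR for one distribution."""
    return InequalitySummary(
        gini=gini(dist),
        rr_quantile=quantile_ratio(dist, p),
        rr_intervention=intervention_rr(dist, p),
        p=p,
    )


def lorenz_grid(dist, n: int = 101) -> np.ndarray:
    """Tabulate the population Lorenz curve on n equally spaced shares.

    Returns an (n, 2) array of (population share, cumulative risk share)
    suitable for delimited export and plotting.
    """
    shares = np.linspace(0.0, 1.0, n)
    values = np.array([lorenz_population(dist, s) for s in shares])
    return np.column_stack([shares, values])
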