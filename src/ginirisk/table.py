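"""Per-cancer summary table: packaged inputs, derived columns, plug-in CIs.

The packaged fixture holds the published inputs for 15 common cancers plus
overall cancer from the Nordic twin registry study of Mucci et al. (JAMA
2016): heritability of liability h2, shared-environment variance fraction
env2, absolute lifetime risk, and the MZ twin recurrence risk ratio
lambda_M, all exactly as printed (percent units for the variance fractions
and risk).  From those inputs this module derives, per trait,

* ``gc_h2``     — Gini index of the probit risk distribution (h2, risk);
* ``gc_beta``   — closed-form Gini of the beta fit to (lambda_M, risk);
* ``rr_2020``   — top-vs-bottom 20% mean-risk ratio of the probit model;
* ``rr_interv`` — relative risk after capping the top 20% at the bottom-20%
  mean, probit model.

Percent-to-fraction conversion happens in exactly one place
(:func:`percent_to_fraction`) at the API boundary.
"""

from __future__ import annotations

import importlib.resources
import logging
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import betarisk, inequality
from .exceptions import GiniRiskError, NoConfidenceBoundsError, ParameterDomainError
from .liability import probit_risk_distribution

logger = logging.getLogger(__name__)

FIXTURE_NAME = "nordic_twin_cancers.tsv"

#: Required fixture/user-table columns (percent units for h2/env2/risk).
REQUIRED_COLUMNS = ("site", "h2_percent", "env2_percent", "lifetime_risk_percent")
OPTIONAL_COLUMNS = (
    "lambda_m",
    "h2_lo_percent",
    "h2_hi_percent",
    "lambda_m_lo",
    "lambda_m_hi",
)

#: Printed precision of each derived column: (decimals, as_integer).
_ROUNDING = {
    "gc_h2": 2,
    "gc_beta": 2,
    "rr_interv": 2,
    "rr_2020": 0,
}


def percent_to_fraction(value: float) -> float:
    """Convert a percent (0-100) to a fraction (0-1); the only such division."""
    if not (0.0 <= value <= 100.0):
        raise ParameterDomainError(f"percent value out of [0, 100]: {value!r}")
    return value / 100.0


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero, matching hand-printed tables."""
    factor = 10.0**decimals
    return float(np.floor(np.abs(value) * factor + 0.5) / factor * np.sign(value))


@dataclass(frozen=True)
class CancerSummaryRecord:
    """One trait: published inputs plus (optionally) derived inequality columns.

    Inputs are stored as fractions; ``lambda_m`` and the confidence bounds
    are optional.  Derived columns are ``None`` until :func:`derive_all`
    fills them.
    """

    site: str
    h2: float
    env2: float
    lifetime_risk: float
    lambda_m: float | None = None
    h2_lower: float | None = None
    h2_upper: float | None = None
    lambda_m_lower: float | None = None
    lambda_m_upper: float | None = None
    gc_h2: float | None = None
    gc_beta: float | None = None
    rr_2020: float | None = None
    rr_interv: float | None = None

    def __post_init__(self) -> None:
        for name in ("h2", "env2"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterDomainError(
                    f"{self.site}: {name} must lie in [0, 1), got {v!r}"
                )
        if not (0.0 < self.lifetime_risk < 1.0):
            raise ParameterDomainError(
                f"{self.site}: lifetime_risk must lie in (0, 1), "
                f"got {self.lifetime_risk!r}"
            )
        if self.lambda_m is not None and self.lambda_m < 1.0:
            raise ParameterDomainError(
                f"{self.site}: lambda_m must be >= 1, got {self.lambda_m!r}"
            )


def _record_from_row(row: pd.Series, index) -> CancerSummaryRecord:
    def opt(name, convert=lambda x: x):
        if name not in row or pd.isna(row[name]):
            return None
        return convert(float(row[name]))

    try:
        return CancerSummaryRecord(
            site=str(row["site"]),
            h2=percent_to_fraction(float(row["h2_percent"])),
            env2=percent_to_fraction(float(row["env2_percent"])),
            lifetime_risk=percent_to_fraction(float(row["lifetime_risk_percent"])),
            lambda_m=opt("lambda_m"),
            h2_lower=opt("h2_lo_percent", percent_to_fraction),
            h2_upper=opt("h2_hi_percent", percent_to_fraction),
            lambda_m_lower=opt("lambda_m_lo"),
            lambda_m_upper=opt("lambda_m_hi"),
        )
    except (ValueError, TypeError, KeyError) as exc:
        raise ParameterDomainError(f"row {index}: {exc}") from exc


def load_table(source=None) -> list[CancerSummaryRecord]:
    """Load trait records from a TSV/CSV file, or the packaged fixture.

    ``source`` may be a path or file-like object; ``None`` loads the
    packaged 16-row table (15 cancer sites plus overall cancer).  The
    delimiter is sniffed from the header line; h2/env2/lifetime risk are
    expected in percent, lambda_m as a plain ratio.
    """
    if source is None:
        resource = importlib.resources.files("ginirisk.data") / FIXTURE_NAME
        with importlib.resources.as_file(resource) as path:
            frame = pd.read_csv(path, sep="\t")
    else:
        frame = pd.read_csv(source, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParameterDomainError(
            f"input table is missing required column(s): {', '.join(missing)}"
        )
    if frame.empty:
        raise ParameterDomainError("input table contains no rows")
    return [_record_from_row(row, idx) for idx, row in frame.iterrows()]


def derive_all(record: CancerSummaryRecord, p: float = 0.2) -> CancerSummaryRecord:
    """Fill the derived inequality columns of one record.

    ``gc_h2``, ``rr_2020`` and ``rr_interv`` come from the probit model at
    (h2, lifetime risk); ``gc_beta`` from the beta fit to (lambda_m,
    lifetime risk) and is left ``None`` when lambda_m is absent.  Beta
    infeasibility is re-raised with the trait name attached.
    """
    probit = probit_risk_distribution(record.h2, record.lifetime_risk)
    gc_h2 = inequality.gini(probit)
    rr_2020 = inequality.quantile_ratio(probit, p)
    rr_interv = inequality.intervention_rr(probit, p)

    gc_beta = None
    if record.lambda_m is not None:
        try:
            beta_dist = betarisk.beta_risk_from_twin_data(
                betarisk.BetaTwinInputs(
                    lambda_m=record.lambda_m,
                    lifetime_risk=record.lifetime_risk,
                )
            )
        except GiniRiskError as exc:
            raise type(exc)(f"{record.site}: {exc}") from exc
        if isinstance(beta_dist, betarisk.BetaRiskDistribution):
            gc_beta = betarisk.gini_beta(beta_dist)
        else:  # lambda_m == 1: degenerate, no inequality
            gc_beta = 0.0
    return replace(
        record, gc_h2=gc_h2, gc_beta=gc_beta, rr_2020=rr_2020, rr_interv=rr_interv
    )


@dataclass(frozen=True)
class PlugInBounds:
    """Plug-in confidence bounds: a metric evaluated at parameter CI limits.

    ``lower_value``/``upper_value`` are ordered so that lower <= upper; if
    the metric decreased in the parameter the evaluations are swapped (and
    a warning logged), so the interval always brackets monotone metrics.
    """

    metric: str
    parameter: str
    lower_param: float
    upper_param: float
    lower_value: float
    upper_value: float
    point_value: float


def _metric_at(record: CancerSummaryRecord, metric: str, **overrides) -> float:
    trial = replace(record, **overrides)
    derived = derive_all(trial)
    return getattr(derived, metric)


def propagate_bounds(record: CancerSummaryRecord, metric: str) -> PlugInBounds:
    """Plug parameter confidence limits into a derived metric.

    ``gc_h2``, ``rr_2020`` and ``rr_interv`` use the h2 bounds (lifetime
    risk held fixed); ``gc_beta`` uses the lambda_m bounds.  Records
    without the relevant bounds raise :class:`NoConfidenceBoundsError`
    ("no CI available") rather than returning zeros.
    """
    if metric not in _ROUNDING:
        raise ParameterDomainError(f"unknown metric {metric!r}")
    if metric == "gc_beta":
        param = "lambda_m"
        lo, hi = record.lambda_m_lower, record.lambda_m_upper
    else:
        param = "h2"
        lo, hi = record.h2_lower, record.h2_upper
    if lo is None or hi is None:
        raise NoConfidenceBoundsError(
            f"{record.site}: no CI available for {param} ({metric})"
        )
    point = _metric_at(record, metric)
    v_lo = _metric_at(record, metric, **{param: lo})
    v_hi = _metric_at(record, metric, **{param: hi})
    if v_lo > v_hi:
        logger.warning(
            "%s: %s is decreasing in %s over the CI; bounds swapped",
            record.site,
            metric,
            param,
        )
        v_lo, v_hi = v_hi, v_lo
    return PlugInBounds(
        metric=metric,
        parameter=param,
        lower_param=lo,
        upper_param=hi,
        lower_value=v_lo,
        upper_value=v_hi,
        point_value=point,
    )


def reproduce_table(
    records=None,
    p: float = 0.2,
    rounded: bool = False,
) -> pd.DataFrame:
    """Derive the inequality columns for every record and return a table.

    ``records=None`` uses the packaged fixture.  The output echoes the
    inputs (percent units, as printed) and appends the derived columns,
    unrounded by default; ``rounded=True`` applies the printed precision
    (2 decimals for Gini and intervention RR, nearest integer for the
    quantile ratio).  Per-trait failures are captured in an ``error``
    column and do not abort the run.
    """
    if records is None:
        records = load_table()
    rows = []
    for record in records:
        start = time.perf_counter()
        row = {
            "site": record.site,
            "h2_percent": record.h2 * 100.0,
            "env2_percent": record.env2 * 100.0,
            "lifetime_risk_percent": record.lifetime_risk * 100.0,
            "lambda_m": record.lambda_m,
            "error": "",
        }
        try:
            derived = derive_all(record, p=p)
            for col in ("gc_h2", "gc_beta", "rr_2020", "rr_interv"):
                value = getattr(derived, col)
                if value is not None and rounded:
                    value = round_half_up(value, _ROUNDING[col])
                row[col] = value
        except GiniRiskError as exc:
            row.update({c: None for c in ("gc_h2", "gc_beta", "rr_2020", "rr_interv")})
            row["error"] = str(exc)
        logger.debug(
            "derived %s in %.3f s", record.site, time.perf_counter() - start
        )
        rows.append(row)
    return pd.DataFrame(rows)
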