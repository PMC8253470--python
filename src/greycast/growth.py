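"""Relative growth rate, doubling time and synthetic indices.

For a cumulative series C_t (running total of annual deaths) the relative
growth rate over one year is

    RGR(t) = ln C_t - ln C_{t-1}

and the doubling-time statistic is the transform

    Dt(RGR) = ln(2 / RGR) = ln 2 - ln RGR,

a strictly decreasing function of RGR that is zero at RGR = 2 and negative
beyond.  Because consecutive running totals of positive annual counts always
satisfy C_t > C_{t-1}, RGR is strictly positive on real data and Dt is
always defined.

A synthetic index blends the mean metric over the observed window with the
mean over the forecast window,

    value = theta * observed_mean + (1 - theta) * forecast_mean,

with equal weights (theta = 0.5) by default.  Countries are ranked
descending by RGR (faster growth first) and ascending by Dt (less time
first); since Dt is a strictly decreasing transform of RGR the two orders
coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DomainError
from .timeseries_io import AnnualSeries

__all__ = [
    "GrowthRecord",
    "SyntheticIndex",
    "RankingEntry",
    "rgr_series",
    "doubling_time",
    "mean_window",
    "synthetic_index",
    "rank_countries",
]


@dataclass(frozen=True)
class GrowthRecord:
    """Cumulative total, RGR and Dt for one year of one country.

    ``rgr`` is None for the first year of a series (no predecessor); ``dt``
    is None wherever RGR is undefined or non-positive.
    """

    year: int
    cumulative: float
    rgr: float | None
    dt: float | None


@dataclass(frozen=True)
class SyntheticIndex:
    theta: float
    original_mean: float
    forecast_mean: float
    value: float


@dataclass(frozen=True)
class RankingEntry:
    label: str
    value: float
    rank: int


def rgr_series(series: AnnualSeries) -> list[GrowthRecord]:
    """Per-year cumulative totals with RGR and Dt.

    The cumulative column is the running total of the annual values; RGR is
    defined from the second year onwards (unit time step, so the 1/(t2-t1)
    factor is 1).
    """
    if len(series) < 2:
        raise DomainError(f"{series.label}: need at least 2 years for RGR")
    cum = np.cumsum(series.values_array())
    records = [GrowthRecord(series.years[0], float(cum[0]), None, None)]
    for i in range(1, len(cum)):
        rgr = float(np.log(cum[i] / cum[i - 1]))
        dt = doubling_time(rgr) if rgr > 0 else None
        records.append(GrowthRecord(series.years[i], float(cum[i]), rgr, dt))
    return records


def doubling_time(rgr: float) -> float:
    """The doubling-time statistic ln(2/RGR) in years; requires RGR > 0."""
    if not rgr > 0:
        raise DomainError(f"doubling time requires RGR > 0, got {rgr}")
    return math.log(2.0 / rgr)


def mean_window(
    records: Iterable[GrowthRecord],
    metric: str,
    start_year: int,
    end_year: int,
) -> float:
    """Arithmetic mean of ``rgr`` or ``dt`` over an inclusive year window."""
    if metric not in ("rgr", "dt"):
        raise ValueError(f"metric must be 'rgr' or 'dt', got {metric!r}")
    values = [
        getattr(r, metric)
        for r in records
        if start_year <= r.year <= end_year and getattr(r, metric) is not None
    ]
    if not values:
        raise DomainError(
            f"no {metric} values in window {start_year}-{end_year}"
        )
    return float(np.mean(values))


def synthetic_index(
    original_mean: float, forecast_mean: float, theta: float = 0.5
) -> SyntheticIndex:
    """Theta-weighted blend of observed-window and forecast-window means."""
    if not 0.0 <= theta <= 1.0:
        raise DomainError(f"theta must lie in [0, 1], got {theta}")
    value = theta * original_mean + (1.0 - theta) * forecast_mean
    return SyntheticIndex(theta, original_mean, forecast_mean, value)


def rank_countries(
    values: Mapping[str, float] | Sequence[tuple[str, float]],
    direction: str = "descending",
) -> list[RankingEntry]:
    """Rank labelled metric values; ties broken by label, alphabetically.

    Use ``descending`` for RGR (greater growth first) and ``ascending`` for
    Dt (less time first).
    """
    if direction not in ("descending", "ascending"):
        raise ValueError(f"direction must be ascending or descending, got {direction!r}")
    items = list(values.items()) if isinstance(values, Mapping) else list(values)
    if not items:
        raise DomainError("nothing to rank")
    sign = -1.0 if direction == "descending" else 1.0
    ordered = sorted(items, key=lambda kv: (sign * kv[1], kv[0]))
    return [
        RankingEntry(label=k, value=v, rank=i + 1)
        for i, (k, v) in enumerate(ordered)
    ]
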