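"""The non-homogeneous discrete grey model NDGM(1,1).

Grey forecasting works on the *accumulated* series.  Writing ``x0`` for the
raw annual counts and ``x1`` for their running totals (the accumulated
generating operation, AGO), the NDGM posits the discrete recursion

    x1_hat(L+1) = beta1 * x1_hat(L) + beta2 * L + beta3,    L = 1 .. n-1
    x1_hat(1)   = x1(1) + beta4

so the accumulated series grows like a geometric term plus a linear drift —
"non-homogeneous exponential" growth.  (beta1, beta2, beta3) are estimated
by ordinary least squares on the n-1 one-step equations; beta4 shifts the
initial condition and is chosen to minimise the sum of squared errors of the
simulated accumulated series.  Annual values are restored from the fitted
accumulated trajectory by first differences (inverse AGO), with the first
restored value taken to be x1_hat(1) itself.

The model is designed for short series (n of the order of 10-20) where
classical time-series machinery has too little data to work with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import FitScore, mape
from .exceptions import (
    DomainError,
    InsufficientDataError,
    SingularSystemError,
    ValidationError,
)
from .timeseries_io import AnnualSeries

__all__ = [
    "AccumulatedSeries",
    "NDGMParameters",
    "NDGMFit",
    "ago",
    "restore",
    "build_regression_system",
    "estimate_linear_params",
    "estimate_shift",
    "fit",
    "forecast",
]

MIN_SERIES_LENGTH = 4  # three one-step equations for three linear parameters


@dataclass(frozen=True)
class AccumulatedSeries:
    """Running totals x1(k) = sum_{i<=k} x0(i) of an annual series."""

    label: str
    years: tuple[int, ...] = field(repr=False)
    values: tuple[float, ...] = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.years) != len(self.values) or not self.years:
            raise ValidationError(f"{self.label}: malformed accumulated series")

    def __len__(self) -> int:
        return len(self.years)

    def values_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class NDGMParameters:
    """The four fitted NDGM coefficients.

    beta1 is the dimensionless recursion multiplier, beta2 the linear drift
    per year index, beta3 the intercept and beta4 the initial-condition
    shift (all but beta1 in the units of the accumulated series).
    """

    beta1: float
    beta2: float
    beta3: float
    beta4: float

    def __post_init__(self):
        for name in ("beta1", "beta2", "beta3", "beta4"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} is not finite")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.beta1, self.beta2, self.beta3, self.beta4)


@dataclass(frozen=True)
class NDGMFit:
    """A fitted NDGM: parameters, trajectories and fit error."""

    series: AnnualSeries
    params: NDGMParameters
    fitted_order1: tuple[float, ...]
    restored: AnnualSeries
    residuals: tuple[float, ...]
    mape_percent: float

    def score(self, skip_first: bool = False) -> FitScore:
        """MAPE of the restored values against the observed series."""
        return mape(
            self.series.values_array(),
            self.restored.values_array(),
            skip_first=skip_first,
        )


def ago(series: AnnualSeries) -> AccumulatedSeries:
    """Accumulated generating operation: raw annual counts -> running totals."""
    return AccumulatedSeries(
        series.label, series.years, tuple(np.cumsum(series.values_array()))
    )


def restore(acc: AccumulatedSeries) -> AnnualSeries:
    """Inverse AGO: first value kept, then first differences.

    ``restore(ago(x)) == x`` for every valid annual series.
    """
    x1 = acc.values_array()
    x0 = np.diff(x1, prepend=0.0)
    x0[0] = x1[0]
    return AnnualSeries(acc.label, acc.years, tuple(x0))


def build_regression_system(acc: AccumulatedSeries) -> tuple[np.ndarray, np.ndarray]:
    """One-step design matrix and response for the NDGM least squares.

    Row L (L = 1 .. n-1) is ``(x1(L), L, 1)`` with response ``x1(L+1)``.
    """
    n = len(acc)
    if n < MIN_SERIES_LENGTH:
        raise InsufficientDataError(
            f"{acc.label}: NDGM needs at least {MIN_SERIES_LENGTH} points, got {n}"
        )
    x1 = acc.values_array()
    L = np.arange(1, n, dtype=float)
    design = np.column_stack([x1[:-1], L, np.ones(n - 1)])
    response = x1[1:]
    return design, response


def estimate_linear_params(
    design: np.ndarray, response: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares estimate of (beta1, beta2, beta3).

    Solved by SVD on a column-equilibrated copy of the design for numerical
    stability; the result coincides with the textbook normal-equation
    solution (B'B)^-1 B'Y on well-conditioned systems.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    if design.ndim != 2 or design.shape[1] != 3 or design.shape[0] < 3:
        raise ValidationError("design must have shape (>=3, 3)")
    if design.shape[0] != response.shape[0]:
        raise ValidationError("design and response lengths differ")
    scale = np.linalg.norm(design, axis=0)
    if np.any(scale == 0):
        raise SingularSystemError("design has a zero column")
    beta_scaled, _, rank, _ = np.linalg.lstsq(design / scale, response, rcond=None)
    if rank < 3:
        raise SingularSystemError(
            "rank-deficient design (accumulated series may be degenerate)"
        )
    b1, b2, b3 = beta_scaled / scale
    return float(b1), float(b2), float(b3)


def _simulate_order1(
    x1_start: float, beta1: float, beta2: float, beta3: float, n: int,
    start_index: int = 1,
) -> np.ndarray:
    """Run the order-1 recursion for n points starting from x1_start.

    ``start_index`` is the year index L of the starting point, so forecasts
    can continue a trajectory mid-stream with the correct drift term.
    """
    z = np.empty(n)
    z[0] = x1_start
    for i in range(1, n):
        L = start_index + i - 1
        z[i] = beta1 * z[i - 1] + beta2 * L + beta3
    return z


def estimate_shift(
    acc: AccumulatedSeries, beta1: float, beta2: float, beta3: float
) -> float:
    """SSE-minimising initial-condition shift beta4.

    With x1_hat(1) = x1(1) + beta4, the simulated trajectory depends on
    beta4 linearly: x1_hat(k) = z(k) + beta4 * beta1**(k-1), where z is the
    recursion seeded at the observed x1(1).  The unique minimiser of
    sum_{k>=2} (x1(k) - x1_hat(k))**2 is therefore the scalar least-squares
    projection

        beta4 = sum_k d_k w_k / sum_k w_k**2,
        d_k = x1(k) - z(k),  w_k = beta1**(k-1).

    This form is exact for every beta1, including beta1 == 1 where the
    geometric-sum expansion of the trajectory would be 0/0.
    """
    for b in (beta1, beta2, beta3):
        if not np.isfinite(b):
            raise ValidationError("non-finite beta passed to estimate_shift")
    x1 = acc.values_array()
    n = len(x1)
    if n < 2:
        raise InsufficientDataError("need at least two accumulated points")
    z = _simulate_order1(x1[0], beta1, beta2, beta3, n)
    w = beta1 ** np.arange(n, dtype=float)
    d = x1[1:] - z[1:]
    denom = float(np.sum(w[1:] ** 2))
    if denom == 0 or not np.isfinite(denom):
        raise DomainError(f"degenerate beta1={beta1}: shift is unidentifiable")
    return float(np.sum(d * w[1:]) / denom)


def fit(series: AnnualSeries) -> NDGMFit:
    """Fit the NDGM(1,1) to an annual series.

    Estimates the three linear coefficients by least squares on the
    accumulated series, the initial-condition shift by SSE minimisation,
    simulates the accumulated trajectory from x1(1) + beta4, restores annual
    values by inverse AGO and attaches the all-points MAPE.
    """
    acc = ago(series)
    design, response = build_regression_system(acc)
    try:
        b1, b2, b3 = estimate_linear_params(design, response)
    except SingularSystemError:
        # A collinear design (e.g. a constant annual series, whose running
        # total is exactly linear) leaves the coefficients unidentifiable.
        # If the one-step equations are still exactly satisfiable, any
        # solution reproduces the data; take the minimum-norm one.
        sol, _, _, _ = np.linalg.lstsq(design, response, rcond=None)
        scale = float(np.max(np.abs(response)))
        if not np.allclose(design @ sol, response, rtol=1e-9, atol=1e-8 * scale):
            raise
        b1, b2, b3 = (float(v) for v in sol)
    b4 = estimate_shift(acc, b1, b2, b3)
    params = NDGMParameters(b1, b2, b3, b4)

    n = len(series)
    x1_hat = _simulate_order1(acc.values[0] + b4, b1, b2, b3, n)
    restored = restore(AccumulatedSeries(series.label, series.years, tuple(x1_hat)))
    actual = series.values_array()
    residuals = actual - restored.values_array()
    score = mape(actual, restored.values_array(), skip_first=False)
    return NDGMFit(
        series=series,
        params=params,
        fitted_order1=tuple(x1_hat),
        restored=restored,
        residuals=tuple(residuals),
        mape_percent=score.mape_percent,
    )


def forecast(fit_result: NDGMFit, horizon: int = 8) -> AnnualSeries:
    """Continue the fitted recursion *horizon* years past the observed window.

    The order-1 recursion is extended from the last fitted accumulated value
    and annual counts are restored by differencing against it, so the first
    forecast year is the next recursion step.  The default horizon of 8
    mirrors an eight-year projection window (2020-2027 for a series ending
    in 2019).
    """
    if horizon < 1:
        raise DomainError(f"horizon must be >= 1, got {horizon}")
    params = fit_result.params
    n = len(fit_result.series)
    # start at the last fitted point (index L = n) and step forward
    traj = _simulate_order1(
        fit_result.fitted_order1[-1],
        params.beta1,
        params.beta2,
        params.beta3,
        horizon + 1,
        start_index=n,
    )
    future_values = np.diff(traj)
    first = fit_result.series.last_year + 1
    years = tuple(range(first, first + horizon))
    return AnnualSeries(fit_result.series.label, years, tuple(future_values))
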