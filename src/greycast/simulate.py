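"""Synthetic annual-count series drawn from the NDGM recursion.

The generator inverts the model: it runs the order-1 recursion

    x1(1) = x0 + shift,   x1(L+1) = beta1 * x1(L) + beta2 * L + beta3

restores annual counts by first differences and optionally perturbs each
annual count by multiplicative log-normal noise exp(N(0, sigma^2)).
Multiplicative noise keeps counts positive and mimics proportional
registration error in cause-of-death statistics.  With ``sigma = 0`` the
output lies exactly on the model manifold, so refitting recovers the
generating coefficients to numerical precision — the backbone of the
package's parameter-recovery tests.

Defaults mirror the study setting: fifteen annual values starting in 2005,
growth mildly super-exponential (beta1 a few percent above 1) at a scale of
tens of thousands of deaths per year, noise off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import GenerationError, ValidationError
from .timeseries_io import AnnualSeries

__all__ = ["GeneratorSpec", "generate"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic series.

    beta1, beta2, beta3
        NDGM recursion coefficients (multiplier; drift per year index and
        intercept, in accumulated-count units).
    x0
        First annual count (deaths/year); the recursion is seeded at
        ``x0 + shift``.
    shift
        Planted initial-condition offset (the model's beta4 analogue).
    n_years, first_year
        Series length (>= 4) and calendar origin.
    sigma
        Scale of multiplicative log-normal noise on annual counts; 0 means
        the series satisfies the recursion exactly.
    seed
        Initialises a private random stream; no global state is touched.
    """

    beta1: float = 1.05
    beta2: float = 300.0
    beta3: float = 1500.0
    x0: float = 30000.0
    shift: float = 0.0
    n_years: int = 15
    first_year: int = 2005
    sigma: float = 0.0
    seed: int | None = None
    label: str = "synthetic"

    def __post_init__(self):
        if self.n_years < 4:
            raise ValidationError(f"n_years must be >= 4, got {self.n_years}")
        if self.x0 <= 0:
            raise ValidationError(f"x0 must be positive, got {self.x0}")
        if self.sigma < 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")

    def with_seed(self, seed: int) -> "GeneratorSpec":
        return replace(self, seed=seed)


def generate(spec: GeneratorSpec) -> AnnualSeries:
    """Draw one annual series from the recursion described by *spec*.

    Raises :class:`GenerationError`, naming the first offending year, if the
    chosen coefficients (or a noise draw) would produce a non-positive
    annual count.
    """
    n = spec.n_years
    x1 = np.empty(n)
    x1[0] = spec.x0 + spec.shift
    for i in range(1, n):
        x1[i] = spec.beta1 * x1[i - 1] + spec.beta2 * i + spec.beta3
    x0 = np.diff(x1, prepend=0.0)
    x0[0] = x1[0]

    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        x0 = x0 * np.exp(rng.normal(0.0, spec.sigma, size=n))

    bad = np.nonzero(~(x0 > 0) | ~np.isfinite(x0))[0]
    if bad.size:
        year = spec.first_year + int(bad[0])
        raise GenerationError(
            f"{spec.label}: non-positive annual count in year {year}; "
            "choose coefficients with positive first differences"
        )
    years = tuple(range(spec.first_year, spec.first_year + n))
    return AnnualSeries(spec.label, years, tuple(x0))
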