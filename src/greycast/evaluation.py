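"""Fit scoring by mean absolute percentage error (MAPE).

MAPE(%) = (100 / n) * sum_k |actual_k - predicted_k| / |actual_k|

and the associated accuracy level 100 - MAPE.  Because the NDGM trajectory
is anchored at the first observation (through the initial-condition shift),
scoring can optionally exclude the first point; both conventions appear in
published grey-model work, so the flag is explicit and defaults to scoring
every point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = ["FitScore", "mape"]


@dataclass(frozen=True)
class FitScore:
    mape_percent: float
    accuracy_percent: float
    n_points: int

    def __post_init__(self):
        if self.mape_percent < 0:
            raise ValidationError("MAPE cannot be negative")
        if self.accuracy_percent != 100.0 - self.mape_percent:
            raise ValidationError("accuracy must equal 100 - MAPE")


def mape(actual, predicted, skip_first: bool = False) -> FitScore:
    """Mean absolute percentage error of *predicted* against *actual*.

    Parameters
    ----------
    actual, predicted
        Equal-length sequences; all actual values must be nonzero.
    skip_first
        Exclude the first point (where the model is anchored) from scoring.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValidationError(
            f"actual and predicted must be 1-d and equal length, got {a.shape} vs {p.shape}"
        )
    if skip_first:
        a, p = a[1:], p[1:]
    if a.size == 0:
        raise DomainError("no points left to score")
    if np.any(a == 0):
        raise DomainError("actual values must be nonzero for MAPE")
    value = float(np.mean(np.abs((a - p) / a)) * 100.0)
    return FitScore(mape_percent=value, accuracy_percent=100.0 - value, n_points=int(a.size))
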