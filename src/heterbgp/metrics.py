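"""Forecast error metrics: MAE, MAPE, RMSE, Pearson correlation.

All metrics are computed over every (sample, step) pair in the evaluation
set. MAPE is reported as a ratio (0.05 == 5%), matching how glucose
forecasting results are usually tabulated.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mae", "mape", "rmse", "pearson", "horizon_to_steps"]


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have identical shapes")
    if actual.size == 0:
        raise ValueError("metrics require at least one point")
    return actual, predicted


def mae(actual, predicted) -> float:
    """Mean absolute error."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def mape(actual, predicted, epsilon: float = 0.0) -> float:
    """Mean absolute percentage error, as a ratio.

    Zero actual values are an error unless a positive ``epsilon`` guard is
    supplied explicitly.
    """
    a, p = _paired(actual, predicted)
    if epsilon == 0.0 and np.any(a == 0):
        raise ValueError("MAPE undefined for zero actual values (set epsilon)")
    return float(np.mean(np.abs(a - p) / (np.abs(a) + epsilon)))


def rmse(actual, predicted) -> float:
    """Root mean square error."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def pearson(actual, predicted) -> float:
    """Product-moment correlation between actuals and predictions."""
    a, p = _paired(actual, predicted)
    if a.size < 2:
        raise ValueError("pearson requires at least 2 points")
    if np.std(a) == 0 or np.std(p) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    am, pm = a - a.mean(), p - p.mean()
    return float((am @ pm) / np.sqrt((am @ am) * (pm @ pm)))


def horizon_to_steps(horizon_minutes: int, resolution_minutes: int) -> int:
    """Map a prediction horizon in minutes to forecast steps."""
    if horizon_minutes % resolution_minutes != 0:
        raise ValueError(
            f"horizon {horizon_minutes} min not divisible by "
            f"resolution {resolution_minutes} min"
        )
    steps = horizon_minutes // resolution_minutes
    if steps < 1:
        raise ValueError("horizon must be at least one resolution step")
    return steps
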