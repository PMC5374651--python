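"""QSAR performance metrics and the leave-one-out cross-validation driver.

The cross-validated correlation coefficient

    q2 = 1 - sum_i (y_i - y_pred,i)^2 / sum_i (y_i - ybar)^2

and the standard deviation of error of prediction

    SDEP = sqrt( sum_i (y_i - y_pred,i)^2 / N )

are the model-quality measures; they are linked by the identity
q2 = 1 - N*SDEP^2 / SS_tot.  Note the population (N) denominator in SDEP.
Test-set r2 is the squared Pearson correlation between predicted and
experimental activities (an SS-ratio variant is provided as well).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

#: fit_fn contract used by loo_predict: fit on (X_train, y_train), return a
#: callable mapping an (m, p) matrix to an (m,) prediction vector.
FitFunction = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


@dataclass
class PredictionSet:
    """Paired experimental and predicted activities for N >= 2 compounds."""

    y: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.y_pred = np.asarray(self.y_pred, dtype=float).ravel()
        if self.y.shape != self.y_pred.shape:
            raise ValueError("y and y_pred must have equal length")
        if self.y.size < 2:
            raise ValueError("need at least 2 observations")
        if not (np.isfinite(self.y).all() and np.isfinite(self.y_pred).all()):
            raise ValueError("activities must be finite")

    @property
    def n(self) -> int:
        return self.y.size


def q2(p: PredictionSet) -> float:
    """Cross-validated correlation coefficient; <= 1, may be negative."""
    ss_tot = float(np.sum((p.y - p.y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("q2 undefined for constant experimental activities")
    ss_res = float(np.sum((p.y - p.y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def sdep(p: PredictionSet) -> float:
    """Root-mean-square prediction error with the N denominator."""
    return float(np.sqrt(np.mean((p.y - p.y_pred) ** 2)))


def r2_test(p: PredictionSet) -> float:
    """Squared Pearson correlation between experimental and predicted values."""
    if np.ptp(p.y) == 0.0 or np.ptp(p.y_pred) == 0.0:
        raise ValueError("r2 undefined when either vector has zero variance")
    r = stats.pearsonr(p.y, p.y_pred).statistic
    return float(r * r)


def r2_ss(p: PredictionSet) -> float:
    """Alternative test-set r2 as 1 - SS_res/SS_tot (same formula as q2).

    Unlike the Pearson form this penalises calibration (bias/scale) errors,
    not only lack of correlation.
    """
    return q2(p)


def loo_predict(
    fit_fn: FitFunction, X: np.ndarray, y: np.ndarray
) -> PredictionSet:
    """Leave-one-out predictions: each compound predicted by a model fitted
    on the other n-1, in row order (deterministic, no shuffling).

    ``fit_fn`` must be deterministic given its training data; a failure on
    any fold aborts with the fold index in the error message.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows must match y length")
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 compounds")
    y_pred = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            predict = fit_fn(X[mask], y[mask])
            y_pred[i] = float(np.asarray(predict(X[i : i + 1])).ravel()[0])
        except Exception as exc:  # noqa: BLE001 - re-raise with fold context
            raise RuntimeError(f"model fit failed on LOO fold {i}: {exc}") from exc
        finally:
            mask[i] = True
    return PredictionSet(y=y, y_pred=y_pred)
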