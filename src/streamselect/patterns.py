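"""Activation-pattern projection of classifier weights.

Linear classifier weights are not directly interpretable as sources of
class-specific signal: a sensor can receive a large weight purely for noise
suppression.  Multiplying the weights by the data covariance (the Haufe
transform) yields an *activation pattern* in which large amplitudes do mark
class-informative signal.
"""

from __future__ import annotations

import numpy as np

from .decoding import TimePointClassifier


def activation_pattern(weights: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Project classifier weights through the data covariance.

    ``weights`` is (n_classes, n_sensors) or (n_sensors,); ``data`` is the
    training trials × sensors matrix at the classifier's time point.  The
    covariance is used as-is (no inversion), so rank-deficient inputs are
    fine.  Bilinear: scaling the data by s scales the pattern by s².
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    X = np.asarray(data, dtype=float)
    if w.shape[1] != X.shape[1]:
        raise ValueError("weights and data disagree on the sensor dimension")
    cov = np.cov(X, rowvar=False, ddof=1)
    pattern = w @ cov.T
    return pattern[0] if np.asarray(weights).ndim == 1 else pattern


def classifier_patterns(
    clf: TimePointClassifier, X_train: np.ndarray, raw_units: bool = True
) -> np.ndarray:
    """Activation patterns of a fitted time-point classifier.

    The covariance is computed in the z-scored feature space the weights
    live in (using the classifier's stored normalization, pooled over all
    training trials); ``raw_units=True`` maps the pattern back to raw sensor
    units by re-applying the per-sensor scale.
    """
    Z = (np.asarray(X_train, dtype=float) - clf.scaler_mean_) / clf.scaler_scale_
    pattern = activation_pattern(clf.coef_, Z)
    if raw_units:
        pattern = pattern * clf.scaler_scale_
    return pattern


def window_average_pattern(
    patterns: np.ndarray, train_times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    """Average per-time activation patterns over a training-time window.

    ``patterns`` has training time on its first axis; the window is
    half-open ``[t0, t1)`` like every other window in the package.
    """
    train_times = np.asarray(train_times, dtype=float)
    mask = (train_times >= window[0] - 1e-6) & (train_times < window[1] - 1e-6)
    if not mask.any():
        raise ValueError("empty training-time window")
    return np.asarray(patterns, dtype=float)[mask].mean(axis=0)
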