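"""Per-timepoint multiclass decoding and temporal generalization.

The decoding model follows the standard MVPA recipe for evoked responses:
at every time sample, sensor features are z-scored (statistics from training
trials only), a linear SVM (C = 1) is fitted one-vs-rest with class-balanced
weights, and each one-vs-rest decision value is passed through a Platt
sigmoid fitted on the training data; the per-class sigmoid outputs are
normalized to sum to one, yielding a calibrated *correct-class probability*
whose chance level is 0.25 with four balanced classes.

Temporal generalization trains at time t and tests at every t′, within a
stratified cross-validation so that t and t′ data always come from
independent trials; the same classifiers can be transferred without
refitting to a different task (localizer → RSVP stream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC


# ---------------------------------------------------------------------------
# Platt sigmoid calibration (Platt 1999, with Lin-Weng-Keerthi Newton updates)
# ---------------------------------------------------------------------------


def _platt_fit(decision: np.ndarray, y_bin: np.ndarray) -> tuple[float, float]:
    """Fit sigmoid P(y=1|f) = 1 / (1 + exp(A f + B)) by penalized ML.

    ``y_bin`` is boolean (positive class).  Targets use Platt's Bayesian
    prior correction; the optimizer is the standard backtracking Newton
    iteration, which is deterministic.
    """
    f = np.asarray(decision, dtype=float)
    y = np.asarray(y_bin, dtype=bool)
    prior1 = int(y.sum())
    prior0 = len(y) - prior1
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y, hi, lo)
    a, b = 0.0, np.log((prior0 + 1.0) / (prior1 + 1.0))
    min_step, sigma_reg = 1e-10, 1e-12

    def objective(a_: float, b_: float) -> float:
        z = a_ * f + b_
        # stable log(1 + exp(z)) formulation of the cross-entropy
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                                     (t - 1) * z + np.log1p(np.exp(z)))))

    fval = objective(a, b)
    for _ in range(100):
        z = a * f + b
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        d1 = t - p  # NB: p here is P(y=1) = 1/(1+exp(z)) with z = a f + b
        d2 = p * (1 - p)
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-10 and abs(g2) < 1e-10:
            break
        h11 = float(np.sum(f * f * d2)) + sigma_reg
        h22 = float(np.sum(d2)) + sigma_reg
        h21 = float(np.sum(f * d2))
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g2) / det
        db = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * da + g2 * db
        step = 1.0
        while step >= min_step:
            new_a, new_b = a + step * da, b + step * db
            new_f = objective(new_a, new_b)
            if new_f < fval + 1e-4 * step * gd:
                a, b, fval = new_a, new_b, new_f
                break
            step /= 2.0
        else:
            break
    return a, b


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Time-point classifier
# ---------------------------------------------------------------------------


@dataclass
class TimePointClassifier:
    """One-vs-rest linear SVM at a single time sample, with calibration.

    Weights live in the z-scored feature space; the stored normalization
    (training-data mean/sd per sensor) is applied to any data the classifier
    scores, so no statistics ever come from test trials.
    """

    classes_: np.ndarray
    coef_: np.ndarray          # (n_classes, n_sensors), z-space
    intercept_: np.ndarray     # (n_classes,)
    scaler_mean_: np.ndarray
    scaler_scale_: np.ndarray
    platt_a_: np.ndarray
    platt_b_: np.ndarray
    train_time: float | None = None
    C: float = 1.0

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != len(self.scaler_mean_):
            raise ValueError("sensor dimension mismatch")
        Z = (X - self.scaler_mean_) / self.scaler_scale_
        return Z @ self.coef_.T + self.intercept_

    def proba_from_decision(self, f: np.ndarray) -> np.ndarray:
        """Platt-calibrated, cross-class-normalized probabilities."""
        p = _sigmoid(-(self.platt_a_ * f + self.platt_b_))
        total = p.sum(axis=-1, keepdims=True)
        uniform = 1.0 / len(self.classes_)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, p / np.where(total > 0, total, 1.0), uniform)
        return out

    def predict_proba_z(self, Z: np.ndarray) -> np.ndarray:
        """Probabilities from features already in the normalized space."""
        Z = np.asarray(Z, dtype=float)
        if Z.shape[-1] != self.coef_.shape[1]:
            raise ValueError("sensor dimension mismatch")
        return self.proba_from_decision(Z @ self.coef_.T + self.intercept_)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Calibrated class probabilities; rows sum to one."""
        return self.proba_from_decision(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels: argmax calibrated probability, ties by class order."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=-1)]


def fit_timepoint(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    train_time: float | None = None,
    standardize: bool = True,
) -> TimePointClassifier:
    """Fit the one-vs-rest, class-weighted, z-scored linear SVM at one time.

    Per-sample weights of 1/count(class) equalize the contribution of every
    category to each hyperplane; the decision values on the training trials
    feed a Platt sigmoid for the probabilistic output.  Deterministic given
    the input order (primal liblinear solver).  With ``standardize=False``
    the features are taken as already normalized (the cross-validation and
    transfer drivers normalize each channel-time feature with
    training-trial statistics before calling this).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be trials × sensors")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per class")
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale
    n_classes, n_feat = len(classes), X.shape[1]
    coef = np.empty((n_classes, n_feat))
    intercept = np.empty(n_classes)
    platt_a = np.empty(n_classes)
    platt_b = np.empty(n_classes)
    # each category contributes unit total weight to every one-vs-rest
    # hyperplane, so duplicating a class's trials is an exact no-op
    counts_by_class = dict(zip(classes, counts))
    sample_weight = np.array([1.0 / counts_by_class[c] for c in y])
    for i, c in enumerate(classes):
        y_bin = (y == c).astype(int)
        svm = LinearSVC(C=C, dual=False, tol=1e-7, max_iter=50000)
        svm.fit(Z, y_bin, sample_weight=sample_weight)
        sign = 1.0 if svm.classes_[1] == 1 else -1.0
        coef[i] = sign * svm.coef_[0]
        intercept[i] = sign * svm.intercept_[0]
        f = Z @ coef[i] + intercept[i]
        platt_a[i], platt_b[i] = _platt_fit(f, y_bin.astype(bool))
    return TimePointClassifier(
        classes_=classes, coef_=coef, intercept_=intercept,
        scaler_mean_=mean, scaler_scale_=scale,
        platt_a_=platt_a, platt_b_=platt_b, train_time=train_time, C=C,
    )


def predict_proba(clf: TimePointClassifier, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`TimePointClassifier.predict_proba`."""
    return clf.predict_proba(X)


# ---------------------------------------------------------------------------
# Temporal generalization
# ---------------------------------------------------------------------------


@dataclass
class GeneralizationMatrix:
    """Training-time × testing-time mean correct-class probability."""

    values: np.ndarray
    train_times: np.ndarray
    test_times: np.ndarray
    chance: float = 0.25

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def diagonal(self) -> np.ndarray:
        if len(self.train_times) != len(self.test_times):
            raise ValueError("diagonal undefined for non-square matrices")
        return np.diagonal(self.values)


def _correct_class_index(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(classes, y)
    if not np.array_equal(classes[idx], np.asarray(y)):
        raise ValueError("labels contain classes unseen at training")
    return idx


def _feature_stats(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-(sensor, time) mean and sd over trials; zero sd maps to one."""
    mu = data.mean(axis=0)
    sd = data.std(axis=0)
    return mu, np.where(sd > 0, sd, 1.0)


def cv_temporal_generalization(
    epochs,
    labels: np.ndarray,
    n_folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
    train_times: np.ndarray | None = None,
    diagonal_only: bool = False,
    return_probs: bool = False,
):
    """Cross-validated temporal generalization within one subject.

    For every training time t, classifiers are fitted on 4/5 of the trials
    (stratified) and applied to the held-out trials at every testing time t′,
    with z-scoring refit on the training split of each fold.  Returns a
    :class:`GeneralizationMatrix` of the per-trial correct-class
    probabilities averaged over trials (and, optionally, the full
    train × test × trials × classes probability array).

    With ``diagonal_only=True`` only t = t′ is evaluated and the matrix
    degenerates to a timecourse stored on the diagonal.
    """
    y = np.asarray(labels)
    X = epochs.data
    times = epochs.times
    if train_times is None:
        ti_idx = np.arange(len(times))
    else:
        ti_idx = np.array([int(np.argmin(np.abs(times - t))) for t in train_times])
    classes = np.unique(y)
    n_trials = X.shape[0]
    n_test = len(times)
    correct = np.full((len(ti_idx), 1 if diagonal_only else n_test, n_trials), np.nan)
    probs = None
    if return_probs:
        probs = np.full((len(ti_idx), 1 if diagonal_only else n_test,
                         n_trials, len(classes)), np.nan)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros(n_trials), y):
        y_train = y[train_idx]
        y_test_ci = _correct_class_index(y[test_idx], classes)
        # z-score every channel-time feature with training-trial statistics
        mu, sd = _feature_stats(X[train_idx])
        Ztrain = (X[train_idx] - mu) / sd
        Ztest = (X[test_idx] - mu) / sd
        for row, ti in enumerate(ti_idx):
            clf = fit_timepoint(Ztrain[:, :, ti], y_train, C=C,
                                train_time=float(times[ti]), standardize=False)
            if diagonal_only:
                p = clf.predict_proba_z(Ztest[:, :, ti])
                correct[row, 0, test_idx] = p[np.arange(len(test_idx)), y_test_ci]
                if return_probs:
                    probs[row, 0, test_idx] = p
            else:
                # score all testing times in one vectorized pass
                Zt = np.transpose(Ztest, (0, 2, 1))  # trials × times × sensors
                p = clf.predict_proba_z(Zt)          # trials × times × classes
                correct[row, :, test_idx] = p[np.arange(len(test_idx))[:, None],
                                              np.arange(n_test)[None, :],
                                              y_test_ci[:, None]]
                if return_probs:
                    probs[row, :, test_idx] = p
    values = correct.mean(axis=2)
    if diagonal_only:
        full = np.full((len(ti_idx), len(ti_idx)), np.nan)
        np.fill_diagonal(full, values[:, 0])
        out_mat = GeneralizationMatrix(values=full, train_times=times[ti_idx],
                                       test_times=times[ti_idx])
    else:
        out_mat = GeneralizationMatrix(values=values, train_times=times[ti_idx],
                                       test_times=times)
    if return_probs:
        return out_mat, probs
    return out_mat


def train_classifiers(
    epochs,
    labels: np.ndarray,
    train_times: np.ndarray | None = None,
    C: float = 1.0,
) -> list[TimePointClassifier]:
    """Fit one classifier per requested training time on *all* trials.

    This is the localizer-side model for cross-task transfer: no
    cross-validation is needed because the classifiers are evaluated on a
    different task's trials.
    """
    times = epochs.times
    if train_times is None:
        idx = np.arange(len(times))
    else:
        idx = np.array([int(np.argmin(np.abs(times - t))) for t in train_times])
    y = np.asarray(labels)
    mu, sd = _feature_stats(epochs.data)
    Z = (epochs.data - mu) / sd
    clfs = []
    for ti in idx:
        clf = fit_timepoint(Z[:, :, ti], y, C=C, train_time=float(times[ti]),
                            standardize=False)
        # make the classifier self-contained for raw data at its own time
        clf.scaler_mean_ = mu[:, ti]
        clf.scaler_scale_ = sd[:, ti]
        clfs.append(clf)
    return clfs


def normalize_features(data: np.ndarray) -> np.ndarray:
    """Z-score a trials × sensors × time array per channel-time feature.

    Label-free standardization of a test task's epochs, so that features
    presented to transferred classifiers live on the same scale as the
    normalized features the classifiers were trained on.
    """
    mu, sd = _feature_stats(data)
    return (data - mu) / sd


def transfer_decode(classifiers: list[TimePointClassifier], epochs) -> np.ndarray:
    """Apply pre-trained classifiers to every time sample of new epochs.

    The new epochs are z-scored per channel-time feature (label-free, see
    :func:`normalize_features`); the classifiers are applied without any
    refitting.  Returns a train-time × test-time × trials × classes
    probability array.
    """
    Z = np.transpose(normalize_features(epochs.data), (0, 2, 1))
    out = np.empty((len(classifiers), Z.shape[1], Z.shape[0],
                    len(classifiers[0].classes_)))
    for i, clf in enumerate(classifiers):
        p = clf.predict_proba_z(Z)            # trials × times × classes
        out[i] = np.transpose(p, (1, 0, 2))
    return out


def correct_class_probability(
    probs: np.ndarray, labels: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Extract P(correct class) per trial from a transfer probability array.

    ``probs`` is train × test × trials × classes; returns train × test ×
    trials.
    """
    ci = _correct_class_index(np.asarray(labels), np.asarray(classes))
    return probs[:, :, np.arange(len(ci)), ci]


def per_stimulus_matrix(
    classifiers: list[TimePointClassifier],
    stream_epochs: dict[int, "object"],
    label_column: str = "category",
) -> dict[int, np.ndarray]:
    """Per-stream-position correct-class probability matrices.

    For each position, the "correct class" is that position's own category
    (from the per-stimulus epoch metadata).  Returns ``position -> train ×
    test × trials`` arrays; averaging over trial subsets (lag, target vs
    non-target, guess membership) is left to the caller, which knows the
    conditioning scheme.
    """
    classes = classifiers[0].classes_
    out: dict[int, np.ndarray] = {}
    for pos, ep in stream_epochs.items():
        if ep.meta is None or label_column not in ep.meta.columns:
            raise ValueError(f"position {pos}: missing {label_column!r} labels")
        probs = transfer_decode(classifiers, ep)
        out[pos] = correct_class_probability(probs, ep.meta[label_column].to_numpy(),
                                             classes)
    return out


# ---------------------------------------------------------------------------
# Derived timecourse metrics
# ---------------------------------------------------------------------------


def mean_window(
    values: np.ndarray, test_times: np.ndarray, window: tuple[float, float] = (400.0, 550.0)
) -> np.ndarray:
    """Mean over a half-open testing-time window along the last axis."""
    test_times = np.asarray(test_times, dtype=float)
    mask = (test_times >= window[0] - 1e-6) & (test_times < window[1] - 1e-6)
    if not mask.any():
        raise ValueError("empty testing-time window")
    return np.asarray(values, dtype=float)[..., mask].mean(axis=-1)


def onset_offset(timecourse: np.ndarray, times: np.ndarray) -> tuple[float, float]:
    """Onset/offset of a group-averaged timecourse via the median rule.

    The threshold is the 50th percentile of the timecourse's own values;
    onset is the first time strictly above it and offset the last.  Raises
    ``ValueError`` when no sample exceeds the threshold (e.g. a flat curve).
    """
    tc = np.asarray(timecourse, dtype=float)
    threshold = float(np.median(tc))
    above = np.flatnonzero(tc > threshold)
    if len(above) == 0:
        raise ValueError("no sample strictly above the median; onset/offset undefined")
    return float(times[above[0]]), float(times[above[-1]])
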