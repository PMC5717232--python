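"""Decoding-layer tests: classifier, calibration, generalization, transfer."""

import numpy as np
import pytest
import scipy.optimize
from sklearn.model_selection import StratifiedKFold

from streamselect.data import EpochsData
from streamselect.decoding import (
    GeneralizationMatrix,
    correct_class_probability,
    cv_temporal_generalization,
    fit_timepoint,
    mean_window,
    onset_offset,
    train_classifiers,
    transfer_decode,
)
from streamselect.simulate import (
    SimulationConfig,
    simulate_localizer,
)


def _epochs(data, sfreq=100.0, t0=0.0):
    data = np.asarray(data, dtype=float)
    times = t0 + (1000.0 / sfreq) * np.arange(data.shape[2])
    return EpochsData(data=data, times=times, sfreq=sfreq)


def _four_class_data(rng, n_per_class=30, n_sensors=6, sep=2.0, noise=1.0):
    means = np.zeros((4, n_sensors))
    for c in range(4):
        means[c, c] = sep
    X = np.concatenate([
        means[c] + noise * rng.standard_normal((n_per_class, n_sensors))
        for c in range(4)
    ])
    y = np.repeat(np.arange(4), n_per_class)
    return X, y


class TestFitTimepoint:
    def test_separable_two_class_training_accuracy(self, rng):
        X = np.concatenate([rng.normal(-3, 0.1, (10, 2)),
                            rng.normal(3, 0.1, (10, 2))])
        y = np.repeat([0, 1], 10)
        clf = fit_timepoint(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            fit_timepoint(rng.standard_normal((10, 3)), np.zeros(10))

    def test_nonfinite_features_rejected(self):
        X = np.zeros((6, 2))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            fit_timepoint(X, np.repeat([0, 1], 3))

    def test_shuffled_labels_give_chance_probability(self, rng):
        """With labels carrying no information the held-out correct-class
        probability sits at chance = 0.25 for four classes."""
        X = rng.standard_normal((160, 6))
        y = rng.permutation(np.repeat(np.arange(4), 40))
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        probs = []
        for tr, te in skf.split(X, y):
            clf = fit_timepoint(X[tr], y[tr])
            p = clf.predict_proba(X[te])
            probs.extend(p[np.arange(len(te)), y[te]])
        assert abs(np.mean(probs) - 0.25) < 0.03

    def test_class_weighting_makes_duplication_a_noop(self, rng):
        """Duplicating every trial of one class leaves the balanced-weight
        hyperplane unchanged (the per-class weights renormalize exactly)."""
        X, y = _four_class_data(rng, n_per_class=20)
        dup = np.concatenate([X, X[y == 2]])
        y_dup = np.concatenate([y, y[y == 2]])
        # fixed normalization: duplication must not perturb the z-statistics
        # for the comparison to be exact
        a = fit_timepoint(X, y, standardize=False)
        b = fit_timepoint(dup, y_dup, standardize=False)
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-6)
        np.testing.assert_allclose(a.intercept_, b.intercept_, atol=1e-6)

    def test_hyperplane_matches_qp_oracle(self, rng):
        """The fitted hyperplane solves the same margin objective as an
        independent optimizer: min 1/2||w_aug||^2 + C sum c_i max(0, 1-y f)^2
        on the intercept-augmented, class-weighted problem."""
        n, d = 20, 3
        X = rng.standard_normal((n, d))
        y = np.array([0] * 8 + [1] * 12)
        clf = fit_timepoint(X, y, C=1.0)
        Z = (X - clf.scaler_mean_) / clf.scaler_scale_
        Zaug = np.hstack([Z, np.ones((n, 1))])
        sign = np.where(y == 1, 1.0, -1.0)
        # class-equalizing weights: each class contributes unit total weight
        cw = np.where(y == 1, 1 / 12, 1 / 8)

        def objective(v):
            margins = np.maximum(0.0, 1.0 - sign * (Zaug @ v))
            return 0.5 * v @ v + 1.0 * np.sum(cw * margins**2)

        res = scipy.optimize.minimize(objective, np.zeros(d + 1),
                                      method="BFGS",
                                      options={"gtol": 1e-10, "maxiter": 2000})
        v = res.x
        fitted = np.concatenate([clf.coef_[1], [clf.intercept_[1]]])
        np.testing.assert_allclose(fitted, v, atol=2e-4)


class TestPredictProba:
    def test_rows_sum_to_one(self, rng):
        X, y = _four_class_data(rng)
        clf = fit_timepoint(X, y)
        p = clf.predict_proba(rng.standard_normal((50, 6)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_ranking_matches_calibrated_decision_values(self, rng):
        """Within a trial, ordering classes by normalized probability equals
        ordering by the per-class calibrated sigmoid outputs."""
        X, y = _four_class_data(rng)
        clf = fit_timepoint(X, y)
        Xt = rng.standard_normal((40, 6))
        f = clf.decision_function(Xt)
        sig = 1.0 / (1.0 + np.exp(clf.platt_a_ * f + clf.platt_b_))
        p = clf.predict_proba(Xt)
        np.testing.assert_array_equal(np.argsort(p, axis=1),
                                      np.argsort(sig, axis=1))

    def test_probability_monotone_in_margin(self, rng):
        """Larger decision value -> larger calibrated per-class probability."""
        X, y = _four_class_data(rng)
        clf = fit_timepoint(X, y)
        assert np.all(clf.platt_a_ < 0)  # sigmoid increasing in the margin

    def test_symmetric_point_gets_uniform_probability(self, rng):
        """A perfectly class-symmetric problem scores its centre at 0.25."""
        base = rng.standard_normal((20, 4))
        X = np.concatenate([base + 3 * np.eye(4)[c] for c in range(4)])
        y = np.repeat(np.arange(4), 20)
        # symmetrize: same trials rotated into each class
        clf = fit_timepoint(X, y)
        centre = clf.scaler_mean_[None, :]
        p = clf.predict_proba(centre)
        np.testing.assert_allclose(p, 0.25, atol=0.05)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _four_class_data(rng)
        clf = fit_timepoint(X, y)
        with pytest.raises(ValueError, match="mismatch"):
            clf.predict_proba(np.zeros((3, 5)))


class TestTemporalGeneralization:
    def test_pure_noise_matrix_at_chance(self, rng):
        ep = _epochs(rng.standard_normal((80, 5, 8)))
        y = np.repeat(np.arange(4), 20)
        mat = cv_temporal_generalization(ep, y, seed=1)
        assert abs(np.nanmean(mat.values) - 0.25) < 0.03

    def test_diagonal_consistency_with_dedicated_run(self, rng):
        """The matrix diagonal equals an independent train=test-time run."""
        ep = _epochs(rng.standard_normal((40, 4, 6)))
        y = np.repeat(np.arange(4), 10)
        full = cv_temporal_generalization(ep, y, seed=2)
        diag = cv_temporal_generalization(ep, y, seed=2, diagonal_only=True)
        np.testing.assert_allclose(np.diagonal(full.values),
                                   np.diagonal(diag.values), atol=1e-12)

    def test_generalization_shape_matches_kernel_overlap(self, kernels):
        """Above-chance (train, test) cells appear exactly where the injected
        response carries a shared stage topography at both times.

        The oracle is exact for orthogonal stage topographies and noise-free
        data: with zero kernel overlap the features carry no component along
        any training topography, the decision values collapse to the
        intercepts, and balanced test folds average to chance exactly.
        """
        from streamselect.simulate import CATEGORIES, PATTERN_STAGES, CategoryPatternSet
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.standard_normal((30, 12)))
        pat = {c: {s: Q[:, i * 3 + j]
                   for j, s in enumerate(PATTERN_STAGES)}
               for i, c in enumerate(CATEGORIES)}
        ortho = CategoryPatternSet(patterns=pat, n_sensors=30)
        cfg = SimulationConfig(n_sensors=30, n_localizer_trials=40,
                               noise_sd=0.0, localizer_sustain_gain=0.0)
        loc = simulate_localizer(cfg, ortho, kernels,
                                 rng=np.random.default_rng(4))
        y = loc.meta["category"].to_numpy()
        probe_trains = [160.0, 280.0, 500.0]
        mat = cv_temporal_generalization(loc, y, seed=0,
                                         train_times=np.array(probe_trains))
        stages = ["early", "mid", "late"]
        for i, t_train in enumerate(probe_trains):
            k_train = {s: kernels.evaluate(s, np.array([t_train]))[0]
                       for s in stages}
            k_test = {s: kernels.evaluate(s, mat.test_times) for s in stages}
            overlap = sum(k_train[s] * k_test[s] for s in stages)
            no_signal = sum(k_test[s] for s in stages) == 0.0
            values = mat.values[i]
            # shared stage at both times -> above chance
            assert np.all(values[overlap > 0.25] > 0.27), t_train
            # signal-free test times -> chance exactly (balanced folds)
            np.testing.assert_allclose(values[no_signal], 0.25, atol=1e-9)
            # other-stage signal, no shared stage -> never above chance
            # (below-chance generalization is possible and expected)
            assert np.all(values[(overlap == 0.0) & ~no_signal] < 0.26), t_train

    def test_off_diagonal_generalization_within_late_window(self, kernels,
                                                            patterns30):
        """The sustained late response generalizes across distant times."""
        cfg = SimulationConfig(n_sensors=30, n_localizer_trials=80,
                               noise_sd=0.3)
        loc = simulate_localizer(cfg, patterns30, kernels,
                                 rng=np.random.default_rng(5))
        y = loc.meta["category"].to_numpy()
        mat = cv_temporal_generalization(loc, y, seed=0,
                                         train_times=np.array([400.0]))
        j = int(np.argmin(np.abs(mat.test_times - 520.0)))
        assert mat.values[0, j] > 0.30

    def test_matches_explicit_train_only_reference(self, rng):
        """Shipped CV output equals a hand-rolled loop whose normalization
        and calibration can only see training trials (leakage regression)."""
        ep = _epochs(rng.standard_normal((40, 4, 5)))
        y = np.repeat(np.arange(4), 10)
        mat, probs = cv_temporal_generalization(ep, y, seed=9,
                                                return_probs=True)
        skf = StratifiedKFold(5, shuffle=True, random_state=9)
        expected = np.full_like(probs, np.nan)
        for tr, te in skf.split(np.zeros(40), y):
            mu = ep.data[tr].mean(axis=0)
            sd = ep.data[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Ztr = (ep.data[tr] - mu) / sd
            Zte = (ep.data[te] - mu) / sd
            for ti in range(5):
                clf = fit_timepoint(Ztr[:, :, ti], y[tr], standardize=False)
                for tj in range(5):
                    expected[ti, tj, te] = clf.predict_proba_z(Zte[:, :, tj])
        np.testing.assert_allclose(probs, expected, atol=1e-12)


class TestTransfer:
    def test_transfer_on_training_task_matches_direct_prediction(self, rng):
        ep = _epochs(rng.standard_normal((30, 4, 6)))
        y = np.tile(np.arange(2), 15)
        clfs = train_classifiers(ep, y, train_times=np.array([20.0, 40.0]))
        probs = transfer_decode(clfs, ep)
        assert probs.shape == (2, 6, 30, 2)
        t_idx = 2  # classifier trained at 20 ms applied at its own time
        direct = clfs[0].predict_proba(ep.data[:, :, t_idx])
        np.testing.assert_allclose(probs[0, t_idx], direct, atol=1e-12)

    def test_rows_remain_normalized(self, rng):
        ep = _epochs(rng.standard_normal((10, 4, 6)))
        y = np.tile(np.arange(2), 5)
        clfs = train_classifiers(ep, y, train_times=np.array([0.0]))
        probs = transfer_decode(clfs, ep)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-9)

    def test_label_permutation_bookkeeping(self, rng):
        """Swapping the category labels permutes which probability column is
        read out as 'correct', and nothing else."""
        ep = _epochs(rng.standard_normal((12, 4, 3)))
        y_train = np.tile(np.arange(4), 5)
        train_ep = _epochs(rng.standard_normal((20, 4, 3)))
        clfs = train_classifiers(train_ep, y_train,
                                 train_times=np.array([10.0]))
        probs = transfer_decode(clfs, ep)
        classes = clfs[0].classes_
        labels = rng.integers(0, 4, 12)
        swapped = (labels + 1) % 4
        cc = correct_class_probability(probs, labels, classes)
        cc_swapped = correct_class_probability(probs, swapped, classes)
        manual = probs[:, :, np.arange(12), swapped]
        np.testing.assert_array_equal(cc_swapped, manual)
        assert not np.allclose(cc, cc_swapped)


class TestWindowMetrics:
    def test_constant_row(self):
        times = np.arange(0.0, 910.0, 10.0)
        assert mean_window(np.full(91, 0.3), times) == pytest.approx(0.3)

    def test_window_400_550_averages_15_samples(self):
        times = np.arange(0.0, 910.0, 10.0)
        values = np.zeros(91)
        mask = (times >= 400) & (times < 550)
        assert mask.sum() == 15
        values[mask] = 1.0
        # mean over exactly the 15 in-window samples
        assert mean_window(values, times) == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_window(np.zeros(10), np.arange(10.0) * 10, (2000.0, 2100.0))


class TestOnsetOffset:
    def test_median_rule_example(self):
        tc = np.array([0.25, 0.25, 0.30, 0.40, 0.30, 0.25, 0.25])
        times = np.arange(7) * 10.0
        onset, offset = onset_offset(tc, times)
        assert (onset, offset) == (20.0, 40.0)

    def test_monotone_series_offsets_at_last_sample(self):
        tc = np.linspace(0.2, 0.6, 9)
        times = np.arange(9) * 10.0
        onset, offset = onset_offset(tc, times)
        assert offset == times[-1]

    def test_flat_series_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            onset_offset(np.full(5, 0.25), np.arange(5) * 10.0)


class TestGeneralizationMatrix:
    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            GeneralizationMatrix(values=np.array([[1.2]]),
                                 train_times=np.array([0.0]),
                                 test_times=np.array([0.0]))
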