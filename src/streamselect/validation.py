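"""Calibration and recovery probes for the whole pipeline.

Each function runs an end-to-end experiment with known ground truth and
returns the measured quantities: permutation null calibration, statistical
oracle agreement (independent brute-force enumerations recomputed at run
time), activation-pattern recovery, behavioral closed forms, and blinded
identification of the selection model.  They complement the recovery
experiments in :mod:`streamselect.pipeline` (overlap separability, gradual
and discrete recovery).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import scipy.stats

from .decoding import train_classifiers
from .patterns import classifier_patterns
from .pipeline import ExperimentConfig, identify_model
from .simulate import (
    CATEGORIES,
    SelectionModel,
    SimulationConfig,
    make_category_patterns,
    make_response_kernels,
    simulate_behavior,
    simulate_localizer,
)
from .stats import art_rm_anova, fdr_adjust, signed_rank_test


def signed_rank_oracle_check(n_datasets: int = 1000, seed: int = 0,
                             max_n: int = 12) -> dict:
    """Exact signed-rank test vs full sign-assignment enumeration.

    The oracle enumerates all 2^n sign assignments of the ranked absolute
    differences from scratch (ties mid-ranked, zeros dropped) and counts
    assignments with W at least as large as observed.
    """
    rng = np.random.default_rng(seed)
    w_mismatches = 0
    max_p_error = 0.0
    checked = 0
    while checked < n_datasets:
        n = int(rng.integers(5, max_n + 1))
        x = np.round(rng.standard_normal(n) * 2, 1)  # rounding induces ties
        if np.all(x == 0):
            continue
        d = x[x != 0]
        ranks = scipy.stats.rankdata(np.abs(d))
        w_oracle = ranks[d > 0].sum()
        sums = np.array([ranks[np.array(s, dtype=bool)].sum()
                         for s in itertools.product([0, 1], repeat=len(d))])
        p_oracle = float(np.mean(sums >= w_oracle - 1e-12))
        res = signed_rank_test(x, tail="greater")
        w_mismatches += int(res.statistic != w_oracle)
        max_p_error = max(max_p_error, abs(res.p_raw - p_oracle))
        checked += 1
    return {"n_datasets": n_datasets, "w_mismatches": w_mismatches,
            "max_p_error": max_p_error}


def fdr_oracle_check(n_families: int = 200, seed: int = 0) -> dict:
    """BH adjustment vs the hand step-up formula on random families."""
    rng = np.random.default_rng(seed)
    max_error = 0.0
    for _ in range(n_families):
        m = int(rng.integers(1, 60))
        p = rng.random(m)
        order = np.argsort(p)
        stepped = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        max_error = max(max_error, float(np.max(np.abs(fdr_adjust(p) - expected))))
    return {"n_families": n_families, "max_abs_error": max_error}


def art_interaction_type1(n_reps: int = 5000, n_subjects: int = 15,
                          seed: int = 0, alpha: float = 0.05) -> dict:
    """Empirical size of the ART interaction test under a null with both
    main effects present (2 x 2 within-subject design, unit noise)."""
    rng = np.random.default_rng(seed)
    cells = [(i, j, k) for i in range(n_subjects)
             for j in range(2) for k in range(2)]
    hits = 0
    for _ in range(n_reps):
        table = (rng.standard_normal((n_subjects, 2, 2))
                 + np.array([0.0, 1.5])[None, :, None]
                 + np.array([0.0, -1.0])[None, None, :])
        df = pd.DataFrame([{"subject": i, "A": j, "B": k, "y": table[i, j, k]}
                           for i, j, k in cells])
        res = art_rm_anova(df, "y", "subject", ("A", "B"))
        hits += res["A:B"].p_raw < alpha
    return {"n_reps": n_reps, "rate": hits / n_reps, "alpha": alpha}


def pattern_recovery(noise_sd: float = 0.1, n_trials: int = 200,
                     seed: int = 0, train_time: float = 160.0) -> dict:
    """Recover injected early-stage topographies via activation patterns.

    Simulates a high-SNR localizer, trains the one-vs-rest classifier at the
    early-stage peak and projects its weights through the data covariance.
    The ground-truth forward pattern of a one-vs-rest discriminant is the
    *contrast* of injected topographies, a_c - mean(a_other): that is the
    spatial signature of the class-c-vs-rest mean difference the classifier
    measures, so the cosine is computed against it.  (The raw single
    category map caps near 0.87 by construction for near-orthogonal
    topographies, however clean the data.)
    """
    cfg = SimulationConfig(n_sensors=30, n_localizer_trials=n_trials,
                           noise_sd=noise_sd, rng_seed=seed)
    kernels = make_response_kernels(sfreq=cfg.sfreq)
    patterns = make_category_patterns(cfg.n_sensors, rng_seed=seed + 1)
    loc = simulate_localizer(cfg, patterns, kernels,
                             rng=np.random.default_rng(seed + 2))
    y = loc.meta["category"].to_numpy()
    clf = train_classifiers(loc, y, train_times=np.array([train_time]))[0]
    t_idx = int(np.argmin(np.abs(loc.times - train_time)))
    recovered = classifier_patterns(clf, loc.data[:, :, t_idx])
    cosines = {}
    for i, c in enumerate(clf.classes_):
        others = [patterns.topography(d, "early") for d in CATEGORIES if d != c]
        contrast = patterns.topography(c, "early") - np.mean(others, axis=0)
        v = recovered[i]
        cosines[c] = float(abs(v @ contrast)
                           / (np.linalg.norm(v) * np.linalg.norm(contrast)))
    values = np.array(list(cosines.values()))
    return {"per_class": cosines, "min_cosine": float(values.min()),
            "mean_cosine": float(values.mean()), "n_trials": n_trials,
            "noise_sd": noise_sd}


def uniform_guesser_accuracy(n_trials: int = 50000, seed: int = 0) -> dict:
    """Monte-Carlo blink accuracy of a pure guesser vs the closed form.

    Three guesses without replacement among 12 positions hit the target
    with probability 1 - (11/12)(10/11)(9/10) = 1/4 exactly.
    """
    rng = np.random.default_rng(seed)
    model = SelectionModel(guess_floor=1.0)
    hits = 0
    for _ in range(n_trials):
        if 7 in simulate_behavior(model, 7, rng, lag=7):
            hits += 1
    return {"n_trials": n_trials, "accuracy": hits / n_trials,
            "closed_form": 0.25}


def identification_config(seed: int, mode: str) -> ExperimentConfig:
    """Reduced-size configuration for one blinded identification run."""
    sim = SimulationConfig(n_sensors=30, n_localizer_trials=200,
                           n_rsvp_trials=60, n_subjects=4, rng_seed=seed)
    return ExperimentConfig(sim=sim, model=SelectionModel(mode=mode))


def model_identification(n_pairs: int = 10, seed: int = 0) -> dict:
    """Blinded gradual-vs-discrete calls over paired simulations.

    For each pair, one gradual and one discrete dataset are generated with
    the same seed and labelled from the early-vs-late window-mean signature
    alone; returns the fraction of correct calls.
    """
    calls = []
    for i in range(n_pairs):
        for mode in ("gradual", "discrete"):
            cfg = identification_config(seed + 1000 * i, mode)
            calls.append(identify_model(cfg) == mode)
    return {"n_runs": len(calls), "rate": float(np.mean(calls))}
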