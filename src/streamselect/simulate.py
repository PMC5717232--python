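"""Forward simulation of localizer and RSVP recordings with known ground truth.

The generative model emulates a rapid-serial-visual-presentation (RSVP)
experiment recorded with a multi-sensor array (MEG-like, but with a single
homogeneous sensor set).  Each stimulus category (face, place, body, object)
drives a sequence of processing *stages*, each with its own sensor topography
and temporal response kernel:

* ``early``    — transient occipito-temporal response, ~90–230 ms;
* ``mid``      — intermediate response, ~220–330 ms;
* ``late``     — sustained late response, ~350–720 ms;
* ``sustain``  — an attention-gated sustained extension of the *early* stage
  (440–720 ms) that re-uses the early-stage topography.  This is the component
  whose amplification distinguishes the gradual-selection hypothesis.

Sensor signals are linear superpositions of the per-stimulus, per-stage
components plus i.i.d. Gaussian sensor noise.  Attentional selection enters
through :class:`SelectionModel`: under the *gradual* hypothesis the sustain
gain follows a graded (asymmetric Gaussian) profile over stream positions
around the target; under the *discrete* hypothesis only reported stimuli
receive a non-zero late-stage gain, graded by guess order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import EpochsData

logger = logging.getLogger(__name__)

#: The four target categories used for decoding (the stream's first item, T1,
#: is a color patch and contributes no category signal).
CATEGORIES: tuple[str, ...] = ("face", "place", "body", "object")

#: Stages that own a topography of their own.
PATTERN_STAGES: tuple[str, ...] = ("early", "mid", "late")

#: All response stages (``sustain`` shares the ``early`` topography).
STAGES: tuple[str, ...] = ("early", "mid", "late", "sustain")

DEFAULT_STAGE_WINDOWS: dict[str, tuple[float, float]] = {
    "early": (90.0, 230.0),
    "mid": (220.0, 330.0),
    "late": (350.0, 720.0),
    "sustain": (440.0, 720.0),
}

#: Half-width (ms) of the skirt outside a stage window within which the kernel
#: may be non-zero.
KERNEL_SKIRT_MS = 50.0


# ---------------------------------------------------------------------------
# Category topographies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryPatternSet:
    """Unit-norm sensor topographies, one per (category, stage) pair.

    ``patterns[c][s]`` is the topography of category ``c`` at stage ``s`` for
    the stages in :data:`PATTERN_STAGES`; the ``sustain`` stage maps onto the
    ``early`` topography via :meth:`topography`.
    """

    patterns: dict[str, dict[str, np.ndarray]]
    n_sensors: int

    def topography(self, category: str, stage: str) -> np.ndarray:
        if stage == "sustain":
            stage = "early"
        return self.patterns[category][stage]

    def as_matrix(self) -> np.ndarray:
        """Stack all 12 topographies into a (12, n_sensors) array."""
        return np.stack(
            [self.patterns[c][s] for c in CATEGORIES for s in PATTERN_STAGES]
        )


def make_category_patterns(
    n_sensors: int, rng_seed: int = 0, max_cosine: float = 0.3
) -> CategoryPatternSet:
    """Draw random unit-norm topographies with bounded pairwise similarity.

    Vectors are sampled sequentially from an isotropic Gaussian and accepted
    only if the absolute cosine similarity with every previously accepted
    topography stays below ``max_cosine``; each slot is given 1000 attempts.

    Raises
    ------
    ValueError
        If ``n_sensors`` is below twice the number of (category, stage) pairs.
    RuntimeError
        If the similarity bound cannot be met within 1000 attempts.
    """
    n_pairs = len(CATEGORIES) * len(PATTERN_STAGES)
    if n_sensors < 2 * n_pairs:
        raise ValueError(
            f"n_sensors={n_sensors} too low: need at least {2 * n_pairs} sensors "
            f"for {n_pairs} near-orthogonal topographies"
        )
    rng = np.random.default_rng(rng_seed)
    accepted: list[np.ndarray] = []
    for _ in range(n_pairs):
        for attempt in range(1000):
            v = rng.standard_normal(n_sensors)
            v /= np.linalg.norm(v)
            if all(abs(v @ u) < max_cosine for u in accepted):
                accepted.append(v)
                break
        else:
            raise RuntimeError(
                f"could not sample topography {len(accepted) + 1}/{n_pairs} with "
                f"|cosine| < {max_cosine} in 1000 attempts"
            )
    patterns = {
        c: {s: accepted[i * len(PATTERN_STAGES) + j] for j, s in enumerate(PATTERN_STAGES)}
        for i, c in enumerate(CATEGORIES)
    }
    return CategoryPatternSet(patterns=patterns, n_sensors=n_sensors)


# ---------------------------------------------------------------------------
# Response kernels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseKernelSet:
    """Per-stage temporal response envelopes.

    Each kernel is a non-negative closed-form envelope of the post-onset lag
    tau (ms), zero outside ``[onset - skirt, offset + skirt]`` and with a
    continuous-time maximum of 1.  Transient stages (``early``, ``mid``) are
    truncated-Gaussian bumps peaking at the window midpoint; sustained stages
    (``late``, ``sustain``) are plateaus with raised-cosine ramps.
    """

    stage_windows: dict[str, tuple[float, float]]
    sfreq: float
    skirt_ms: float = KERNEL_SKIRT_MS

    def evaluate(self, stage: str, tau_ms: np.ndarray) -> np.ndarray:
        """Evaluate the stage kernel at lags ``tau_ms`` (vectorized)."""
        onset, offset = self.stage_windows[stage]
        tau = np.asarray(tau_ms, dtype=float)
        lo, hi = onset - self.skirt_ms, offset + self.skirt_ms
        inside = (tau >= lo) & (tau <= hi)
        out = np.zeros_like(tau)
        if stage in ("early", "mid"):
            center = 0.5 * (onset + offset)
            sd = (0.5 * (offset - onset) + self.skirt_ms) / 3.0
            out[inside] = np.exp(-0.5 * ((tau[inside] - center) / sd) ** 2)
        else:
            k = np.zeros_like(tau)
            rise = inside & (tau < onset)
            fall = inside & (tau > offset)
            flat = inside & ~rise & ~fall
            k[rise] = 0.5 * (1.0 - np.cos(np.pi * (tau[rise] - lo) / self.skirt_ms))
            k[fall] = 0.5 * (1.0 + np.cos(np.pi * (tau[fall] - offset) / self.skirt_ms))
            k[flat] = 1.0
            out = k
        return out

    def sample(self, stage: str, tmax_ms: float = 900.0) -> np.ndarray:
        """Kernel values on the regular grid 0..tmax_ms at ``sfreq``."""
        dt = 1000.0 / self.sfreq
        grid = np.arange(0.0, tmax_ms + 0.5 * dt, dt)
        return self.evaluate(stage, grid)


def make_response_kernels(
    stage_windows: dict[str, tuple[float, float]] | None = None,
    sfreq: float = 100.0,
) -> ResponseKernelSet:
    """Build the per-stage response kernels, validating the stage windows."""
    windows = dict(DEFAULT_STAGE_WINDOWS if stage_windows is None else stage_windows)
    for stage, (onset, offset) in windows.items():
        if not (0.0 <= onset < offset <= 900.0):
            raise ValueError(
                f"stage {stage!r}: window ({onset}, {offset}) must satisfy "
                "0 <= onset < offset <= 900 ms"
            )
    return ResponseKernelSet(stage_windows=windows, sfreq=float(sfreq))


# ---------------------------------------------------------------------------
# Selection models and behavior
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionModel:
    """Attentional-gain model over stream positions.

    In ``gradual`` mode the sustain-stage gain of stimulus at position ``i``
    is ``gradual_amplitude * exp(-d^2 / (2 sigma_side^2))`` with
    ``d = i - target``; the left (preceding-stimulus) width is
    ``gradual_sigma`` and the right width ``gradual_sigma *
    gradual_asymmetry`` (asymmetric toward preceding positions).  The late
    stage is silent.

    In ``discrete`` mode the sustain stage is silent and the late-stage gain
    is ``discrete_gain * guess_gains[rank]`` for reported stimuli (rank =
    guess order) and exactly 0 for all others.

    ``lag_modulation`` scales both the attentional gain and the behavioral
    attention weight per inter-target lag (the attentional blink: weaker
    selection at short lags).
    """

    mode: str = "gradual"
    gradual_sigma: float = 1.2
    gradual_amplitude: float = 2.0
    gradual_asymmetry: float = 0.25
    discrete_gain: float = 2.0
    guess_gains: tuple[float, float, float] = (1.0, 0.7, 0.4)
    lag_modulation: dict[int, float] = field(
        default_factory=lambda: {1: 0.8, 3: 0.55, 7: 0.85, 9: 1.0}
    )
    behavior_sigma: float = 1.2
    guess_floor: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("gradual", "discrete"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.gradual_amplitude < 0 or self.discrete_gain < 0:
            raise ValueError("gains must be non-negative")

    def lag_gain(self, lag: int) -> float:
        return float(self.lag_modulation.get(lag, 1.0))

    def gradual_profile(self, positions: np.ndarray, target: int) -> np.ndarray:
        """Graded sustain gain over stream positions (before lag modulation)."""
        d = np.asarray(positions, dtype=float) - float(target)
        sigma_left = self.gradual_sigma
        sigma_right = max(self.gradual_sigma * self.gradual_asymmetry, 1e-12)
        sigma = np.where(d <= 0, sigma_left, sigma_right)
        return self.gradual_amplitude * np.exp(-0.5 * (d / sigma) ** 2)

    def stage_gains(
        self, positions: np.ndarray, target: int, lag: int, guesses: list[int]
    ) -> dict[str, np.ndarray]:
        """Per-position gain for each response stage on one trial."""
        positions = np.asarray(positions)
        ones = np.ones(len(positions))
        gains = {"early": ones, "mid": ones.copy()}
        lag_g = self.lag_gain(lag)
        if self.mode == "gradual":
            gains["sustain"] = lag_g * self.gradual_profile(positions, target)
            gains["late"] = np.zeros(len(positions))
        else:
            gains["sustain"] = np.zeros(len(positions))
            late = np.zeros(len(positions))
            for rank, g in enumerate(guesses):
                late[positions == g] = lag_g * self.discrete_gain * self.guess_gains[rank]
            gains["late"] = late
        return gains

    def report_weights(self, target: int, lag: int, n_positions: int = 12) -> np.ndarray:
        """Probability distribution of Guess 1 over stream positions 1..12.

        A mixture of an attention-driven component centred on the target
        (discretized Gaussian in gradual mode, point mass in discrete mode)
        and a uniform guessing floor.  The attention weight shrinks with
        ``lag_modulation`` and ``guess_floor``.
        """
        positions = np.arange(1, n_positions + 1)
        if self.mode == "gradual":
            sigma = max(self.behavior_sigma, 1e-9)
            core = np.exp(-0.5 * ((positions - target) / sigma) ** 2)
        else:
            core = (positions == target).astype(float)
        core_sum = core.sum()
        core = core / core_sum if core_sum > 0 else np.full(n_positions, 1.0 / n_positions)
        alpha = self.lag_gain(lag) * (1.0 - self.guess_floor)
        alpha = float(np.clip(alpha, 0.0, 1.0))
        return alpha * core + (1.0 - alpha) / n_positions


def simulate_behavior(
    model: SelectionModel,
    target_position: int,
    rng: np.random.Generator,
    n_guesses: int = 3,
    lag: int | None = None,
) -> list[int]:
    """Draw ``n_guesses`` distinct position reports for one trial.

    Guesses are sampled sequentially without replacement from the model's
    report distribution over stream positions 1..12, renormalized after each
    draw — i.e. successive guesses behave as samples from one underlying
    attentional distribution centred on the target.
    """
    if not 1 <= target_position <= 12:
        raise ValueError("target_position must be in 1..12")
    lag = target_position if lag is None else lag
    weights = model.report_weights(target_position, lag).copy()
    positions = np.arange(1, 13)
    guesses: list[int] = []
    for _ in range(n_guesses):
        total = weights.sum()
        if total > 0:
            p = weights / total
        else:  # degenerate point-mass model: remaining mass is uniform
            p = np.array([0.0 if g in guesses else 1.0 for g in positions])
            p /= p.sum()
        g = int(rng.choice(positions, p=p))
        guesses.append(g)
        weights[g - 1] = 0.0
    return guesses


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants and simulation sizes.

    Defaults mirror the emulated experiment (8.6 Hz stream: SOA 116 ms,
    stimulus duration 84 ms, 13 stimuli, target lags 1/3/7/9) with recording
    sizes scaled to a sensor array of 30 channels at 100 Hz.
    """

    n_sensors: int = 30
    sfreq: float = 100.0
    soa_ms: float = 116.0
    stim_duration_ms: float = 84.0
    n_stream: int = 13
    lags: tuple[int, ...] = (1, 3, 7, 9)
    n_localizer_trials: int = 200
    n_rsvp_trials: int = 120
    noise_sd: float = 0.8
    n_subjects: int = 15
    rng_seed: int = 0
    max_pattern_cosine: float = 0.3
    localizer_window: tuple[float, float] = (-50.0, 550.0)
    rsvp_window: tuple[float, float] = (-200.0, 2300.0)
    localizer_sustain_gain: float = 1.0

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sfreq

    def times(self, window: tuple[float, float]) -> np.ndarray:
        """Inclusive-endpoint sample grid for an epoch window."""
        t0, t1 = window
        n = int(round((t1 - t0) / self.dt_ms)) + 1
        return t0 + self.dt_ms * np.arange(n)


def stimulus_onsets(config: SimulationConfig) -> np.ndarray:
    """Onset (ms, post-T1) of stream positions 1..n_stream-1, grid-rounded.

    The nominal SOA (116 ms) is not a multiple of the 10 ms sample period at
    100 Hz; onsets are rounded to the nearest sample and these rounded onsets
    are used everywhere downstream (synthesis and re-epoching alike).
    """
    dt = config.dt_ms
    nominal = config.soa_ms * np.arange(1, config.n_stream)
    return np.rint(nominal / dt) * dt


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------


def _localizer_signal(
    category: str,
    times: np.ndarray,
    patterns: CategoryPatternSet,
    kernels: ResponseKernelSet,
    sustain_gain: float,
) -> np.ndarray:
    """Noise-free single-stimulus signal, (n_sensors, n_times)."""
    sig = np.zeros((patterns.n_sensors, len(times)))
    for stage in STAGES:
        gain = sustain_gain if stage == "sustain" else 1.0
        if gain == 0.0:
            continue
        k = kernels.evaluate(stage, times)
        sig += gain * np.outer(patterns.topography(category, stage), k)
    return sig


def simulate_localizer(
    config: SimulationConfig,
    patterns: CategoryPatternSet,
    kernels: ResponseKernelSet,
    rng: np.random.Generator | None = None,
    subject: int = 0,
) -> EpochsData:
    """Simulate single-stimulus (localizer) epochs with balanced categories.

    Each trial presents one stimulus of one category; its signal is the sum
    of the stage components evaluated on the epoch grid, plus Gaussian sensor
    noise.  Trial labels live in ``meta["category"]``.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = config.n_localizer_trials
    n_cat = len(CATEGORIES)
    per_class = int(round(n / n_cat))
    if n % n_cat:
        logger.warning(
            "n_localizer_trials=%d not divisible by %d; using %d trials",
            n, n_cat, per_class * n_cat,
        )
    labels = np.repeat(np.arange(n_cat), per_class)
    rng.shuffle(labels)
    times = config.times(config.localizer_window)
    clean = {
        c: _localizer_signal(c, times, patterns, kernels, config.localizer_sustain_gain)
        for c in CATEGORIES
    }
    data = np.empty((len(labels), config.n_sensors, len(times)))
    for t, lab in enumerate(labels):
        data[t] = clean[CATEGORIES[lab]]
    data += rng.normal(0.0, config.noise_sd, data.shape)
    meta = pd.DataFrame(
        {"subject": subject, "trial": np.arange(len(labels)),
         "category": [CATEGORIES[lab] for lab in labels]}
    )
    return EpochsData(data=data, times=times, sfreq=config.sfreq, meta=meta)


def simulate_rsvp_trial(
    config: SimulationConfig,
    patterns: CategoryPatternSet,
    kernels: ResponseKernelSet,
    model: SelectionModel,
    lag: int,
    rng: np.random.Generator,
    noise: bool = True,
    categories: list[str] | None = None,
    guesses: list[int] | None = None,
) -> tuple[np.ndarray, dict]:
    """Simulate one RSVP trial: 12 superimposed stimulus responses + behavior.

    Returns the (n_sensors, n_times) signal on the trial grid and a TrialInfo
    row (categories per position, lag, target position, guesses).  Behavior is
    sampled first; in discrete mode the late-stage gains are then conditioned
    on the sampled guesses (graded by guess order).  T1 (position 0) is only a
    timing anchor and contributes no category signal.
    """
    if lag not in config.lags:
        raise ValueError(f"lag {lag} not in configured lags {config.lags}")
    positions = np.arange(1, config.n_stream)
    if categories is None:
        categories = [CATEGORIES[i] for i in rng.integers(0, len(CATEGORIES), len(positions))]
    if guesses is None:
        guesses = simulate_behavior(model, target_position=lag, rng=rng, lag=lag)
    onsets = stimulus_onsets(config)
    times = config.times(config.rsvp_window)
    gains = model.stage_gains(positions, target=lag, lag=lag, guesses=guesses)
    x = np.zeros((config.n_sensors, len(times)))
    for idx, pos in enumerate(positions):
        tau = times - onsets[idx]
        for stage in STAGES:
            g = gains[stage][idx]
            if g == 0.0:
                continue
            k = kernels.evaluate(stage, tau)
            if not np.any(k):
                continue
            x += g * np.outer(patterns.topography(categories[idx], stage), k)
    if noise:
        x += rng.normal(0.0, config.noise_sd, x.shape)
    info = {"lag": lag, "target_pos": lag}
    info.update({f"cat_pos{p}": categories[i] for i, p in enumerate(positions)})
    info.update({f"guess{k + 1}": guesses[k] for k in range(len(guesses))})
    return x, info


def simulate_rsvp(
    config: SimulationConfig,
    patterns: CategoryPatternSet,
    kernels: ResponseKernelSet,
    model: SelectionModel,
    rng: np.random.Generator,
    subject: int = 0,
) -> EpochsData:
    """Simulate a block of RSVP trials with lags balanced and shuffled."""
    n_lag = len(config.lags)
    per_lag = int(round(config.n_rsvp_trials / n_lag))
    if config.n_rsvp_trials % n_lag:
        logger.warning(
            "n_rsvp_trials=%d not divisible by %d lags; using %d trials",
            config.n_rsvp_trials, n_lag, per_lag * n_lag,
        )
    lag_seq = np.repeat(config.lags, per_lag)
    rng.shuffle(lag_seq)
    times = config.times(config.rsvp_window)
    data = np.empty((len(lag_seq), config.n_sensors, len(times)))
    rows = []
    for t, lag in enumerate(lag_seq):
        x, info = simulate_rsvp_trial(config, patterns, kernels, model, int(lag), rng)
        data[t] = x
        info.update({"subject": subject, "trial": t})
        rows.append(info)
    meta = pd.DataFrame(rows)
    lead = ["subject", "trial", "lag", "target_pos"]
    meta = meta[lead + [c for c in meta.columns if c not in lead]]
    return EpochsData(data=data, times=times, sfreq=config.sfreq, meta=meta)


def simulate_dataset(
    config: SimulationConfig, model: SelectionModel
) -> list[dict]:
    """Simulate the full study: per subject, a localizer and an RSVP session.

    Every subject gets independent topographies and noise derived from
    ``config.rng_seed`` via spawned generators, so the output is reproducible
    bit-for-bit from the seed.

    Returns a list of ``{"localizer": EpochsData, "rsvp": EpochsData,
    "trial_info": DataFrame, "patterns": CategoryPatternSet}`` per subject.
    """
    kernels = make_response_kernels(sfreq=config.sfreq)
    root = np.random.SeedSequence(config.rng_seed)
    subjects = []
    for s, seq in enumerate(root.spawn(config.n_subjects)):
        pattern_seed, noise_seed = seq.generate_state(2) >> 1  # keep below 2**31
        patterns = make_category_patterns(
            config.n_sensors, rng_seed=int(pattern_seed), max_cosine=config.max_pattern_cosine
        )
        rng = np.random.default_rng(int(noise_seed))
        localizer = simulate_localizer(config, patterns, kernels, rng, subject=s)
        rsvp = simulate_rsvp(config, patterns, kernels, model, rng, subject=s)
        subjects.append(
            {"localizer": localizer, "rsvp": rsvp, "trial_info": rsvp.meta,
             "patterns": patterns}
        )
    return subjects
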