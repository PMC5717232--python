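"""Epoch containers and light preprocessing.

``EpochsData`` is the universal container: a trials × sensors × time array
with a millisecond time axis and a per-trial metadata table.  Time-window
selection throughout the package is half-open, ``[t0, t1)``: a sample at time
t belongs to a window iff ``t0 <= t < t1``.  Epoch *construction* grids are
inclusive of both endpoints (e.g. −50..550 ms at 100 Hz is 61 samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

_TOL = 1e-6


@dataclass
class EpochsData:
    """Trials × sensors × time array with time axis and trial metadata."""

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × sensors × time")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length mismatch")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1000.0 / self.sfreq, atol=_TOL):
            raise ValueError("times must be uniformly spaced at 1000/sfreq")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.meta is not None and len(self.meta) != self.data.shape[0]:
            raise ValueError("meta length must match number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask for samples with t0 <= t < t1."""
        t0, t1 = window
        return (self.times >= t0 - _TOL) & (self.times < t1 - _TOL)

    def copy(self) -> "EpochsData":
        meta = None if self.meta is None else self.meta.copy()
        return EpochsData(self.data.copy(), self.times.copy(), self.sfreq, meta)


def baseline_correct(epochs: EpochsData, window: tuple[float, float]) -> EpochsData:
    """Subtract the per-trial, per-sensor mean over a pre-onset window.

    The window is half-open and must end at or before time 0.
    """
    if window[1] > _TOL:
        raise ValueError("baseline window must end at or before stimulus onset")
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochsData(epochs.data - baseline, epochs.times.copy(), epochs.sfreq,
                      None if epochs.meta is None else epochs.meta.copy())


def downsample(
    epochs: EpochsData, target_sfreq: float, cutoff_hz: float | None = None
) -> EpochsData:
    """Anti-alias low-pass then decimate to ``target_sfreq``.

    The filter is a zero-phase FIR (Hamming ``firwin`` + ``filtfilt``) with a
    default cutoff of 0.4 × the target Nyquist frequency.  ``target_sfreq``
    must divide ``sfreq``.
    """
    ratio = epochs.sfreq / target_sfreq
    q = int(round(ratio))
    if abs(ratio - q) > _TOL or q < 1:
        raise ValueError("target_sfreq must divide sfreq")
    if q == 1:
        return epochs.copy()
    if cutoff_hz is None:
        cutoff_hz = 0.4 * (target_sfreq / 2.0)
    n = epochs.data.shape[2]
    numtaps = min(301, max(11, (n // 3) - 1))
    if numtaps % 2 == 0:
        numtaps -= 1
    taps = scipy.signal.firwin(numtaps, cutoff_hz, fs=epochs.sfreq)
    padlen = min(3 * numtaps, n - 1)
    filtered = scipy.signal.filtfilt(taps, [1.0], epochs.data, axis=2, padlen=padlen)
    data = filtered[:, :, ::q]
    times = epochs.times[::q]
    return EpochsData(data, times, target_sfreq,
                      None if epochs.meta is None else epochs.meta.copy())


def epoch_stream(
    rsvp: EpochsData,
    onsets: np.ndarray,
    window: tuple[float, float] = (0.0, 900.0),
    positions: list[int] | None = None,
    label_prefix: str = "cat_pos",
) -> dict[int, EpochsData]:
    """Cut one epoch per stream position out of whole-trial RSVP data.

    ``onsets[i]`` is the (grid-rounded) onset of stream position ``i + 1``
    relative to T1.  Each per-stimulus epoch spans ``window`` (inclusive grid,
    time zero at that stimulus's onset) and inherits the trial metadata with a
    ``category`` column taken from ``{label_prefix}{position}`` when present.
    Epochs that would exceed the recorded trial span are dropped with a
    warning.
    """
    onsets = np.asarray(onsets, dtype=float)
    if positions is None:
        positions = list(range(1, len(onsets) + 1))
    dt = 1000.0 / rsvp.sfreq
    n_samp = int(round((window[1] - window[0]) / dt)) + 1
    rel_times = window[0] + dt * np.arange(n_samp)
    out: dict[int, EpochsData] = {}
    for pos in positions:
        onset = onsets[pos - 1]
        start = onset + window[0]
        i0 = int(round((start - rsvp.times[0]) / dt))
        if i0 < 0 or i0 + n_samp > len(rsvp.times):
            warnings.warn(
                f"position {pos}: epoch [{start}, {onset + window[1]}] ms exceeds "
                "recorded trial span; dropped"
            )
            continue
        meta = None
        if rsvp.meta is not None:
            meta = rsvp.meta.copy()
            col = f"{label_prefix}{pos}"
            if col in meta.columns:
                meta["category"] = meta[col]
            meta["position"] = pos
        out[pos] = EpochsData(rsvp.data[:, :, i0:i0 + n_samp].copy(),
                              rel_times.copy(), rsvp.sfreq, meta)
    return out


def moving_average(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving average with truncated edges (display smoothing only).

    Applied along the last axis; length is preserved.  This is never used
    before statistical testing — it exists to smooth exported timecourses.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    n = series.shape[-1]
    if window > n:
        raise ValueError("window longer than series")
    if window == 1:
        return series.copy()
    half = window // 2
    out = np.empty_like(series)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[..., i] = series[..., lo:hi].mean(axis=-1)
    return out
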