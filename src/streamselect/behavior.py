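"""Behavioral report-distribution analysis.

Works on the TrialInfo table produced by the simulator (or loaded from CSV):
one row per trial with the inter-target lag, target position and the three
ordered guesses.  All distributions are over stream positions 1..12.

Chance levels account for guessing without replacement: a uniform guesser's
k-th guess lands on any given position with probability 1/(12 − k + 1)
conditional on it not having been named yet — i.e. 1/12, 1/11, 1/10 for
guesses 1–3.  A flat-1/12 convention can be requested instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_POSITIONS = 12


def chance_level(guess_index: int, convention: str = "without-replacement") -> float:
    """Chance report proportion for guess k (1-based)."""
    if convention == "without-replacement":
        return 1.0 / (N_POSITIONS - guess_index + 1)
    if convention == "flat":
        return 1.0 / N_POSITIONS
    raise ValueError(f"unknown chance convention {convention!r}")


def report_distribution(
    trial_info: pd.DataFrame,
    lag: int,
    guess_index: int,
    chance_convention: str = "without-replacement",
) -> pd.DataFrame:
    """Per-subject report proportions over positions for one lag and guess.

    Returns a tidy frame (subject, position, proportion, chance); each
    subject's proportions sum to one over positions.
    """
    if guess_index not in (1, 2, 3):
        raise ValueError("guess_index must be 1, 2 or 3")
    sub = trial_info[trial_info["lag"] == lag]
    if len(sub) == 0:
        raise ValueError(f"no trials at lag {lag}")
    col = f"guess{guess_index}"
    chance = chance_level(guess_index, chance_convention)
    rows = []
    for subject, grp in sub.groupby("subject"):
        counts = grp[col].value_counts()
        for pos in range(1, N_POSITIONS + 1):
            rows.append({
                "subject": subject, "lag": lag, "guess": guess_index,
                "position": pos,
                "proportion": counts.get(pos, 0) / len(grp),
                "chance": chance,
            })
    return pd.DataFrame(rows)


def distribution_mode_variance(distribution: pd.DataFrame | np.ndarray) -> tuple[int, float]:
    """Mode and variance of a report distribution over positions.

    Accepts a proportion vector over positions 1..12 (or a tidy frame with
    ``position``/``proportion`` columns, averaged over subjects first).
    Mode ties resolve to the earliest position; variance treats positions as
    an integer scale.
    """
    if isinstance(distribution, pd.DataFrame):
        p = (distribution.groupby("position")["proportion"].mean()
             .reindex(range(1, N_POSITIONS + 1), fill_value=0.0).to_numpy())
    else:
        p = np.asarray(distribution, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("empty distribution")
    p = p / total
    positions = np.arange(1, len(p) + 1, dtype=float)
    mode = int(positions[np.argmax(p)])
    mu = float(p @ positions)
    variance = float(p @ (positions - mu) ** 2)
    return mode, variance


def conditional_distribution(
    trial_info: pd.DataFrame,
    lag: int,
    guess1_position: int,
    guess_index: int = 2,
) -> pd.DataFrame:
    """Distribution of a later guess restricted by the Guess-1 report.

    Keeps only trials where Guess 1 named ``guess1_position``; the
    conditioned position is removed from the support (it cannot be named
    again) and proportions are renormalized over the remaining positions.
    """
    if guess_index not in (2, 3):
        raise ValueError("conditional distributions exist for guesses 2 and 3")
    sub = trial_info[(trial_info["lag"] == lag)
                     & (trial_info["guess1"] == guess1_position)]
    if len(sub) == 0:
        raise ValueError(
            f"empty condition: lag={lag}, guess1={guess1_position}")
    col = f"guess{guess_index}"
    support = [p for p in range(1, N_POSITIONS + 1) if p != guess1_position]
    rows = []
    for subject, grp in sub.groupby("subject"):
        counts = grp[col].value_counts()
        for pos in support:
            rows.append({
                "subject": subject, "lag": lag, "guess": guess_index,
                "conditioned_on": guess1_position, "position": pos,
                "proportion": counts.get(pos, 0) / len(grp),
                "chance": 1.0 / len(support),
            })
    return pd.DataFrame(rows)


def blink_accuracy(trial_info: pd.DataFrame) -> pd.DataFrame:
    """Report accuracy per subject and lag.

    A trial counts as correct when any of the three guesses names the target
    position; plotted against lag this traces the attentional blink.
    """
    df = trial_info.copy()
    hit = ((df["guess1"] == df["target_pos"])
           | (df["guess2"] == df["target_pos"])
           | (df["guess3"] == df["target_pos"]))
    df["correct"] = hit.astype(float)
    return (df.groupby(["subject", "lag"])["correct"].mean()
            .rename("accuracy").reset_index())
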