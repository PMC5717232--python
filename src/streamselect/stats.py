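"""Group-level statistics: signed-rank tests, BH-FDR, ART ANOVA, t-tests.

The statistical layer operates on per-subject summary values (random-effects
style).  Tests against chance default to one-sided (greater); contrasts
between conditions default to two-sided.  Multiple-comparison families are
always declared explicitly by the caller and corrected with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

_TAILS = ("greater", "less", "two-sided")


@dataclass
class StatResult:
    """One test outcome: statistic, raw p, and (optionally) FDR-adjusted p."""

    statistic: float
    p_raw: float
    n: int
    test: str
    tail: str
    df: tuple | None = None
    p_fdr: float | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_W(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W (sum of positive-difference ranks) and the midranks of |d|."""
    ranks = scipy.stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_p_greater(ranks: np.ndarray, w_obs: float) -> float:
    """P(W >= w_obs) under random signs, by convolution over rank sums.

    Midranks are multiples of 1/2, so doubling them gives integers and the
    distribution of 2W is a polynomial product computed exactly.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2_obs = int(np.rint(2 * w_obs))
    return float(counts[w2_obs:].sum() / counts.sum())


def signed_rank_test(
    x: np.ndarray, mu: float = 0.0, tail: str = "greater"
) -> StatResult:
    """Wilcoxon signed-rank test of paired differences (or values − chance).

    Zero differences are dropped (Wilcoxon's rule) and ties are mid-ranked.
    The null distribution is enumerated exactly for n <= 15 and approximated
    by a tie-corrected, continuity-corrected normal otherwise.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    d = np.asarray(x, dtype=float) - mu
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        # exact enumeration still works, but the test is nearly powerless
        pass
    w, ranks = _signed_rank_W(d)
    if n <= 15:
        p_greater = _exact_p_greater(ranks, w)
        total = ranks.sum()
        p_less = _exact_p_greater(ranks, total - w)  # symmetry: P(W <= w)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        sd = np.sqrt(var)
        p_greater = float(scipy.stats.norm.sf((w - mean - 0.5) / sd))
        p_less = float(scipy.stats.norm.cdf((w - mean + 0.5) / sd))
    if tail == "greater":
        p = p_greater
    elif tail == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return StatResult(statistic=w, p_raw=float(p), n=n,
                      test="wilcoxon-signed-rank", tail=tail)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg FDR
# ---------------------------------------------------------------------------


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values, in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: list[StatResult], family: str) -> list[StatResult]:
    """Adjust a declared family of StatResults in place; returns the list."""
    adjusted = fdr_adjust([r.p_raw for r in results])
    for r, p in zip(results, adjusted):
        r.p_fdr = float(p)
        r.family = family
    return results


# ---------------------------------------------------------------------------
# ART repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _rm_anova_ranks(
    table: np.ndarray, effect: str
) -> tuple[float, tuple[int, int], float]:
    """Balanced two-way within-subject ANOVA F for one effect.

    ``table`` is subjects × levels(A) × levels(B).  The error term is the
    effect-by-subject interaction, as in a standard repeated-measures ANOVA.
    """
    s, a, b = table.shape
    grand = table.mean()
    m_s = table.mean(axis=(1, 2))
    m_a = table.mean(axis=(0, 2))
    m_b = table.mean(axis=(0, 1))
    m_sa = table.mean(axis=2)
    m_sb = table.mean(axis=1)
    m_ab = table.mean(axis=0)
    if effect == "A":
        ss = s * b * ((m_a - grand) ** 2).sum()
        df = a - 1
        err = b * ((m_sa - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
        df_err = (a - 1) * (s - 1)
    elif effect == "B":
        ss = s * a * ((m_b - grand) ** 2).sum()
        df = b - 1
        err = a * ((m_sb - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
        df_err = (b - 1) * (s - 1)
    elif effect == "A:B":
        inter = m_ab - m_a[:, None] - m_b[None, :] + grand
        ss = s * (inter**2).sum()
        df = (a - 1) * (b - 1)
        resid = (table
                 - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
                 + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
                 - grand)
        err = (resid**2).sum()
        df_err = (a - 1) * (b - 1) * (s - 1)
    else:  # pragma: no cover
        raise ValueError(effect)
    f = (ss / df) / (err / df_err) if err > 0 else np.inf
    return float(f), (df, df_err), float(scipy.stats.f.sf(f, df, df_err))


def align_rank(
    table: np.ndarray, effect: str
) -> np.ndarray:
    """Aligned ranks of a subjects × A × B table for one effect.

    Alignment subtracts the cell mean (stripping every factorial effect) and
    adds back the least-squares estimate of the effect of interest; the
    aligned values are then mid-ranked across the entire dataset.
    """
    grand = table.mean()
    m_s = table.mean(axis=(1, 2))
    m_a = table.mean(axis=(0, 2))
    m_b = table.mean(axis=(0, 1))
    m_ab = table.mean(axis=0)
    # residual strips every estimated effect, including the subject intercept
    resid = table - m_ab[None, :, :] - (m_s - grand)[:, None, None]
    if effect == "A":
        est = (m_a - grand)[None, :, None]
    elif effect == "B":
        est = (m_b - grand)[None, None, :]
    elif effect == "A:B":
        est = (m_ab - m_a[:, None] - m_b[None, :] + grand)[None, :, :]
    else:
        raise ValueError(f"unknown effect {effect!r}")
    aligned = resid + est
    ranks = scipy.stats.rankdata(aligned.ravel()).reshape(aligned.shape)
    return ranks


def art_rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    factors: tuple[str, str],
) -> dict[str, StatResult]:
    """Aligned-rank-transform repeated-measures ANOVA (two within factors).

    For each main effect and the interaction: align the responses for that
    effect (cell-mean alignment), rank the aligned values across the whole
    dataset, and run a standard within-subject ANOVA on the ranks, keeping
    only the statistic for the aligned effect.  Requires a complete balanced
    design — one observation per subject × cell; missing cells are an error.
    """
    fa, fb = factors
    subjects = np.sort(data[subject].unique())
    levels_a = np.sort(data[fa].unique())
    levels_b = np.sort(data[fb].unique())
    table = np.full((len(subjects), len(levels_a), len(levels_b)), np.nan)
    grouped = data.set_index([subject, fa, fb])[dv]
    for (i, su), (j, la), (k, lb) in product(
        enumerate(subjects), enumerate(levels_a), enumerate(levels_b)
    ):
        try:
            val = grouped.loc[(su, la, lb)]
        except KeyError:
            raise ValueError(f"missing cell: {subject}={su}, {fa}={la}, {fb}={lb}")
        if np.ndim(val) > 0:
            raise ValueError("more than one observation per subject × cell")
        table[i, j, k] = val
    effects = {fa: "A", fb: "B", f"{fa}:{fb}": "A:B"}
    out: dict[str, StatResult] = {}
    for name, code in effects.items():
        ranks = align_rank(table, code)
        f, (df1, df2), p = _rm_anova_ranks(ranks, code)
        out[name] = StatResult(statistic=f, p_raw=p, n=len(subjects),
                               test="art-rm-anova", tail="two-sided", df=(df1, df2))
    return out


# ---------------------------------------------------------------------------
# t-test and trend helpers
# ---------------------------------------------------------------------------


def one_sample_ttest(x: np.ndarray, mu: float = 0.0, tail: str = "two-sided") -> StatResult:
    """Classical one-sample t-test with df = n − 1."""
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.std(x, ddof=1) == 0.0:
        raise ValueError("zero variance: t statistic undefined")
    res = scipy.stats.ttest_1samp(x, mu, alternative=tail)
    return StatResult(statistic=float(res.statistic), p_raw=float(res.pvalue),
                      n=len(x), test="one-sample-t", tail=tail, df=(len(x) - 1,))


def linear_trend_slope(
    values: np.ndarray, tail: str = "two-sided"
) -> tuple[np.ndarray, StatResult]:
    """Per-subject least-squares slope over ordered levels + group test.

    ``values`` is subjects × levels, levels ordered (e.g. Guess 1, 2, 3,
    unreported).  Returns the per-subject slopes and a group signed-rank
    test of the slopes against zero.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 3:
        raise ValueError("need at least 3 ordered levels per subject")
    idx = np.arange(values.shape[1], dtype=float)
    slopes = np.polyfit(idx, values.T, deg=1)[0]
    if np.allclose(slopes, 0.0, atol=1e-12):
        # flat profiles carry no evidence of a trend in either direction
        result = StatResult(statistic=0.0, p_raw=1.0, n=len(slopes),
                            test="wilcoxon-signed-rank", tail=tail)
        return slopes, result
    return slopes, signed_rank_test(slopes, tail=tail)


def results_table(results: dict[str, StatResult] | list[StatResult]) -> pd.DataFrame:
    """Long-format table of StatResults for CSV export."""
    items = results.items() if isinstance(results, dict) else enumerate(results)
    rows = []
    for key, r in items:
        rows.append({
            "test_id": key, "test": r.test, "statistic": r.statistic,
            "df": "x".join(str(d) for d in r.df) if r.df else "",
            "p_raw": r.p_raw, "p_fdr": r.p_fdr, "family": r.family,
            "tail": r.tail, "n": r.n,
        })
    return pd.DataFrame(rows)
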