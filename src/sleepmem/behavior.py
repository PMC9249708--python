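"""Recognition-memory scoring: confidence collapse, rates, accuracy, d'.

Confidence ratings (1 = very confident present ... 6 = very confident not
present) collapse at the 3/4 boundary into present / not-present. Per
(subject, condition, test, valence) cell: hit rate = P(present | old),
false-alarm rate = P(present | new), accuracy = % correct over scored
trials, and d' = z(hit) - z(FA) with extreme rates corrected by the
1/(2N) rule before the inverse-normal transform. Buffer trials (primacy/
recency controls) are excluded from all scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "collapse_confidence",
    "dprime",
    "score_sessions",
    "difference_scores",
    "exclude_outliers",
    "table1_summary",
]

CELL_KEYS = ["subject", "condition", "test", "valence"]


def collapse_confidence(confidence) -> str:
    """Map a 1-6 confidence rating to 'present' (1-3) or 'not_present' (4-6)."""
    c = int(confidence)
    if c != confidence or not 1 <= c <= 6:
        raise ValueError(f"confidence must be an integer in 1..6, got {confidence!r}")
    return "present" if c <= 3 else "not_present"


def _correct_rate(rate: float, n: int, correction: str) -> float:
    if correction == "none":
        return rate
    if correction == "half":  # the 1/(2N) rule
        if rate <= 0.0:
            return 1.0 / (2 * n)
        if rate >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate
    raise ValueError(f"unknown correction {correction!r}")


def dprime(hit_rate: float, fa_rate: float, n_targets: int, n_foils: int,
           correction: str = "half") -> float:
    """Signal-detection discriminability d' = z(hit) - z(FA).

    Rates of exactly 0 or 1 are replaced by 1/(2N) or 1 - 1/(2N)
    (``correction='half'``, the default) so the inverse-normal transform
    stays finite; ``correction='none'`` disables this.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_targets < 1 or n_foils < 1:
        raise ValueError("n_targets and n_foils must be >= 1")
    h = _correct_rate(hit_rate, n_targets, correction)
    f = _correct_rate(fa_rate, n_foils, correction)
    return float(norm.ppf(h) - norm.ppf(f))


def _corrected_ppf(rates: np.ndarray, n: np.ndarray,
                   correction: str) -> np.ndarray:
    r = np.asarray(rates, dtype=float).copy()
    if correction == "half":
        n = np.asarray(n, dtype=float)
        r = np.where(r <= 0.0, 1.0 / (2 * n), r)
        r = np.where(r >= 1.0, 1.0 - 1.0 / (2 * n), r)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return norm.ppf(r)


def score_sessions(trials: pd.DataFrame, correction: str = "half",
                   ) -> pd.DataFrame:
    """Score a trial table into per-cell memory measures.

    Expects columns subject, condition, test, valence, status
    (old/new/buffer), confidence. Buffer trials are dropped before
    scoring. Cells missing old or new trials are flagged
    ``complete=False`` with NaN scores.
    """
    conf = pd.to_numeric(trials["confidence"], errors="coerce")
    if not conf.isin([1, 2, 3, 4, 5, 6]).all():
        bad = trials["confidence"][~conf.isin([1, 2, 3, 4, 5, 6])]
        raise ValueError(
            f"confidence must be an integer in 1..6; offending values: "
            f"{bad.unique()[:5]}")
    t = trials.loc[trials["status"].isin(["old", "new"]),
                   CELL_KEYS + ["status"]].copy()
    t["present"] = (conf[t.index] <= 3).to_numpy()
    agg = t.groupby(CELL_KEYS + ["status"], sort=True)["present"] \
           .agg(["mean", "count"]).unstack("status")
    hit = agg.get(("mean", "old"), pd.Series(np.nan, index=agg.index))
    fa = agg.get(("mean", "new"), pd.Series(np.nan, index=agg.index))
    n_t = agg.get(("count", "old"), pd.Series(0, index=agg.index)).fillna(0)
    n_f = agg.get(("count", "new"), pd.Series(0, index=agg.index)).fillna(0)
    t["correct"] = np.where(t["status"] == "old", t["present"], ~t["present"])
    acc = 100.0 * t.groupby(CELL_KEYS, sort=True)["correct"].mean()
    complete = hit.notna() & fa.notna()
    d = np.where(
        complete,
        _corrected_ppf(hit.fillna(0.5), np.maximum(n_t, 1), correction)
        - _corrected_ppf(fa.fillna(0.5), np.maximum(n_f, 1), correction),
        np.nan)
    out = pd.DataFrame({
        "n_targets": n_t.astype(int),
        "n_foils": n_f.astype(int),
        "hit_rate": hit.where(complete),
        "fa_rate": fa.where(complete),
        "accuracy_pct": acc.where(complete),
        "dprime": d,
        "complete": complete,
    }).reset_index()
    return out


def difference_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Test 2 minus test 1 d' per subject x condition x valence.

    Forgetting across the retention interval yields a negative value.
    Cells missing either test are flagged ``complete=False``.
    """
    wide = scores.pivot_table(index=["subject", "condition", "valence"],
                              columns="test", values="dprime", aggfunc="first")
    out = wide.reset_index()
    have_both = out.get(1) is not None and out.get(2) is not None
    if not have_both:
        out["ddprime"] = np.nan
        out["complete"] = False
    else:
        out["ddprime"] = out[2] - out[1]
        out["complete"] = out["ddprime"].notna()
    out = out[["subject", "condition", "valence", "ddprime", "complete"]]
    out.columns.name = None
    return out


def exclude_outliers(values: pd.Series | np.ndarray,
                     sd_criterion: float = 2.5) -> np.ndarray:
    """Boolean keep-mask: True where the value is within +/- k SD of the mean.

    NaNs are kept (they carry their own missing flag). When the SD is zero
    every value is kept.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        return np.ones_like(x, dtype=bool)
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        return np.ones_like(x, dtype=bool)
    keep = np.ones_like(x, dtype=bool)
    keep[finite] = np.abs(x[finite] - mu) <= sd_criterion * sd
    return keep


def table1_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Group means and SDs of hit rate, FA rate and d' per design cell."""
    g = scores.groupby(["condition", "test", "valence"])
    out = g.agg(
        hit_rate_mean=("hit_rate", "mean"), hit_rate_sd=("hit_rate", "std"),
        fa_rate_mean=("fa_rate", "mean"), fa_rate_sd=("fa_rate", "std"),
        dprime_mean=("dprime", "mean"), dprime_sd=("dprime", "std"),
        n=("dprime", "count"),
    ).reset_index()
    return out
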