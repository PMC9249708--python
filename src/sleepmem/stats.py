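"""Inferential layer for the within-subject cross-over design.

The central model is the 2 (drug) x 2 (test) x 2 (emotion) repeated-
measures ANOVA with a mean-centered body-weight covariate. With 2-level
within factors every effect has one numerator degree of freedom, so each
within effect is tested as a regression of the per-subject effect
contrast on [1, centered covariate]: the intercept F tests the within
effect, the slope F its interaction with the covariate (the classic
univariate RM-ANCOVA, the behavior of standard statistical packages).
No sphericity correction is needed (all within factors are 2-level).

Also here: paired t-tests, the Holm-Bonferroni step-down procedure, and
Bonferroni-screened Pearson correlations between sleep features and
memory variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "AnovaResult",
    "PairedTResult",
    "rm_anova_2x2x2",
    "paired_t",
    "holm_bonferroni",
    "sleep_memory_screen",
]

FACTORS = ("drug", "test", "emotion")
#: Long-format column carrying each factor.
FACTOR_COLUMNS = {"drug": "condition", "test": "test", "emotion": "valence"}
#: Level coded +1 (the other level is -1).
_POSITIVE_LEVEL = {"drug": "zolpidem", "test": 2, "emotion": "negative"}


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    n_subjects: int


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float
    degenerate: bool = False


def _ols_coef_tests(y: np.ndarray, X: np.ndarray) -> list[tuple[float, float, int]]:
    """Per-coefficient (F, p, df_den) from an OLS fit."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_den = n - k
    if df_den <= 0:
        return [(np.nan, np.nan, df_den)] * k
    sigma2 = float(resid @ resid) / df_den
    xtx_inv = np.linalg.inv(X.T @ X)
    out = []
    for j in range(k):
        if sigma2 == 0:
            F = 0.0 if beta[j] == 0 else np.inf
        else:
            F = float(beta[j] ** 2 / (sigma2 * xtx_inv[j, j]))
        p = float(sst.f.sf(F, 1, df_den))
        out.append((F, p, df_den))
    return out


def rm_anova_2x2x2(scores: pd.DataFrame, covariate=None,
                   value: str = "dprime") -> list[AnovaResult]:
    """2x2x2 repeated-measures AN(C)OVA on per-cell scores.

    Parameters
    ----------
    scores : DataFrame
        Long format with columns subject, condition (placebo/zolpidem),
        test (1/2), valence (negative/neutral) and the ``value`` column.
    covariate : Series or dict, optional
        One value per subject (e.g. body weight, kg); it is mean-centered
        internally. Constant covariates are dropped, which reduces the
        model to the plain RM-ANOVA.

    Subjects with any missing cell are removed listwise (count reported
    via a warning). Returns one :class:`AnovaResult` per within effect,
    each covariate interaction, and the between-subject covariate effect.
    """
    wide = scores.pivot_table(index="subject",
                              columns=["condition", "test", "valence"],
                              values=value, aggfunc="first")
    n_total = wide.shape[0]
    wide = wide.dropna()
    if wide.shape[1] != 8:
        raise ValueError(
            f"expected 8 within-subject cells, found {wide.shape[1]}")
    n = wide.shape[0]
    if n_total - n:
        warnings.warn(f"listwise deletion removed {n_total - n} of "
                      f"{n_total} subjects with incomplete cells", stacklevel=2)
    if n < 3:
        raise ValueError("need at least 3 complete subjects")

    codes = np.array([
        [+1 if cond == _POSITIVE_LEVEL["drug"] else -1,
         +1 if test == _POSITIVE_LEVEL["test"] else -1,
         +1 if val == _POSITIVE_LEVEL["emotion"] else -1]
        for cond, test, val in wide.columns
    ])
    Y = wide.to_numpy(dtype=float)

    w = None
    if covariate is not None:
        cov = pd.Series(covariate)
        cov = cov.reindex(wide.index)
        if cov.isna().any():
            missing = cov.isna().sum()
            warnings.warn(f"covariate missing for {missing} subjects; "
                          "they are removed listwise", stacklevel=2)
            keep = cov.notna()
            Y, cov = Y[keep.to_numpy()], cov[keep]
            n = Y.shape[0]
        w = cov.to_numpy(dtype=float)
        w = w - w.mean()
        if np.allclose(w, 0.0):
            w = None  # constant covariate: plain RM-ANOVA

    X = np.column_stack([np.ones(n)] if w is None else [np.ones(n), w])
    results: list[AnovaResult] = []

    # between-subject covariate effect on the subject means
    if w is not None:
        tests = _ols_coef_tests(Y.mean(axis=1), X)
        F, p, dfd = tests[1]
        results.append(AnovaResult("weight", F, 1, dfd, p, n))

    for order in (1, 2, 3):
        for combo in combinations(range(3), order):
            sign = np.prod(codes[:, list(combo)], axis=1)
            # scaled so the contrast is a mean difference for main effects
            contrast = Y @ (sign / (len(sign) / 2))
            name = ":".join(FACTORS[i] for i in combo)
            tests = _ols_coef_tests(contrast, X)
            F, p, dfd = tests[0]
            results.append(AnovaResult(name, F, 1, dfd, p, n))
            if w is not None:
                F, p, dfd = tests[1]
                results.append(AnovaResult(f"{name}:weight", F, 1, dfd, p, n))
    return results


def paired_t(x, y) -> PairedTResult:
    """Two-sided paired t-test; df = n - 1.

    Zero-variance difference vectors are flagged degenerate: t = 0 / p = 1
    when the differences are all zero, +/- inf / p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays, n >= 2")
    d = x - y
    n = len(d)
    if np.std(d, ddof=1) == 0:
        if d.mean() == 0:
            return PairedTResult(0.0, n - 1, 1.0, degenerate=True)
        t = np.inf * np.sign(d.mean())
        return PairedTResult(float(t), n - 1, 0.0, degenerate=True)
    res = sst.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), n - 1, float(res.pvalue))


def holm_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm-Bonferroni step-down rejections, in input order.

    Sort ascending; the i-th smallest p is rejected iff every p(j) with
    j <= i satisfies p(j) <= alpha / (m - j) (0-based j).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order[i]] <= alpha / (m - i):
            reject_sorted[i] = True
        else:
            break
    out = np.zeros(m, dtype=bool)
    out[order] = reject_sorted
    return out


def sleep_memory_screen(features: pd.DataFrame, memory: pd.DataFrame,
                        alpha_corrected: float,
                        on: tuple[str, ...] = ("subject", "condition"),
                        ) -> pd.DataFrame:
    """Pearson screen of every sleep feature against every memory variable.

    Both frames must carry the ``on`` key columns; every other numeric
    column is treated as a feature (left frame) or memory variable (right
    frame). Correlations run separately per condition when 'condition' is
    in the keys. Pairs with a constant vector or n < 3 are flagged
    ``valid=False``.
    """
    feat_cols = [c for c in features.columns
                 if c not in on and pd.api.types.is_numeric_dtype(features[c])]
    mem_cols = [c for c in memory.columns
                if c not in on and pd.api.types.is_numeric_dtype(memory[c])]
    merged = features.merge(memory, on=list(on), how="inner")
    group_cols = [c for c in on if c != "subject"]
    groups = merged.groupby(group_cols) if group_cols else [((), merged)]
    rows = []
    for gkey, g in groups:
        if not isinstance(gkey, tuple):
            gkey = (gkey,)
        for f in feat_cols:
            for mv in mem_cols:
                sub = g[[f, mv]].dropna()
                row = dict(zip(group_cols, gkey))
                row.update(feature=f, memory_variable=mv, n=len(sub),
                           alpha_corrected=alpha_corrected)
                if len(sub) < 3 or sub[f].nunique() == 1 or sub[mv].nunique() == 1:
                    row.update(r=np.nan, p=np.nan, significant=False,
                               valid=False)
                else:
                    r, p = sst.pearsonr(sub[f], sub[mv])
                    row.update(r=float(r), p=float(p),
                               significant=bool(p < alpha_corrected),
                               valid=True)
                rows.append(row)
    return pd.DataFrame(rows)
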