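"""Cohort-level statistics for ALPS tables.

Covers the minimal inferential toolkit the index tables feed into: partial
correlation with a single control covariate, ROC analysis with the Youden
cut-off (optionally age-adjusted via residualization), and descriptive
group summaries.  Heavier procedures (ANCOVA, post-hoc corrections) are
expected to be run on the exported CSV with any standard stats package.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

GROUPS = ("CN", "MCI", "AD")


def _residualize(y: np.ndarray, control: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(control), control])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(x, y, control) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for one covariate.

    Both variables are residualized against the control; the correlation of
    the residuals is returned with a two-sided p-value from the t transform
    with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    control = np.asarray(control, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("partial correlation requires n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(control))):
        raise ValueError("inputs must be finite")
    for v in (x, y, control):
        if np.std(v) == 0:
            raise ValueError("zero-variance variable")
    rx = _residualize(x, control)
    ry = _residualize(y, control)
    # a variable fully explained by the control has (numerically) zero residual
    if np.linalg.norm(rx) <= 1e-10 * np.linalg.norm(x - x.mean()) or \
       np.linalg.norm(ry) <= 1e-10 * np.linalg.norm(y - y.mean()):
        return 0.0, 1.0
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    r = float(np.dot(rx, ry) / denom)
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def roc_youden(scores, labels) -> dict:
    """Empirical ROC with the Youden-index optimal cut-off.

    Positive class = label 1, predicted positive when score >= cutoff.
    AUC is the trapezoidal area (equal to the Mann-Whitney statistic with
    ties counted 1/2).  Among cut-offs maximizing J = SE + SP - 1, the one
    with the higher specificity is reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best_j = j.max()
    # ties toward higher specificity = lower FPR (roc_curve sorts by
    # descending threshold, so take the first index attaining the max)
    cand = np.nonzero(np.isclose(j, best_j))[0]
    k = cand[np.argmin(fpr[cand])]
    return {
        "auc": auc,
        "sensitivity": float(tpr[k]),
        "specificity": float(1.0 - fpr[k]),
        "cutoff": float(thr[k]),
        "youden_j": float(best_j),
    }


def roc_youden_age_adjusted(scores, labels, age) -> dict:
    """ROC on residuals of the score after pooled linear age regression.

    One of several possible covariate adjustments; the unadjusted ROC should
    always be reported alongside.
    """
    scores = np.asarray(scores, dtype=float)
    age = np.asarray(age, dtype=float)
    resid = _residualize(scores, age)
    out = roc_youden(resid, labels)
    out["adjustment"] = "age-residualized"
    return out


def group_summary(table: pd.DataFrame, value_cols=None,
                  group_col: str = "group") -> pd.DataFrame:
    """Per-group mean +/- sample SD (n-1) for each ALPS column.

    Returns a tidy frame: one row per (group, variable) with n, mean, sd and
    a formatted "mean +/- sd" string. Empty groups are omitted with a warning.
    """
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id")
    bad = set(table[group_col]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    if value_cols is None:
        value_cols = [
            c for c in table.columns
            if c not in ("subject_id", group_col) and np.issubdtype(table[c].dtype, np.number)
        ]
    rows = []
    for g in GROUPS:
        sub = table[table[group_col] == g]
        if sub.empty:
            warnings.warn(f"group {g} is empty; omitted")
            continue
        for col in value_cols:
            vals = sub[col].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            rows.append(
                dict(group=g, variable=col, n=vals.size, mean=mean, sd=sd,
                     formatted=f"{mean:.3f} ± {sd:.3f}")
            )
    return pd.DataFrame(rows)
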