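"""Shared statistics: multivariate group comparison and composition tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparison:
    feature_set: str
    groups: list[str]
    statistic: float  # Pillai's trace (or max univariate F on fallback)
    p_value: float
    direction: dict[str, int] = field(default_factory=dict)
    dropped_features: list[str] = field(default_factory=list)
    method: str = "pillai"


def _pillai_f(V: float, s: int, m: float, n: float) -> tuple[float, float, float]:
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n + s + 1)
    denom = s - V
    if denom <= 0:
        return np.inf, df1, df2
    F = (df2 / df1) * (V / denom)
    return F, df1, df2


def manova_compare(
    X: pd.DataFrame,
    groups: Sequence,
    feature_set: str = "",
    alpha_bh: Optional[float] = None,
) -> GroupComparison:
    """One-way MANOVA via Pillai's trace with the standard F approximation.

    `X` is samples x features; `groups` the group label per sample.
    Zero-variance features are dropped (and reported). When the pooled
    within-group scatter matrix is singular the comparison falls back to
    feature-wise one-way ANOVA with a Bonferroni-combined p-value and a
    warning. Direction is reported per feature as the sign of
    mean(first group) - mean(second group), groups sorted.
    """
    labels = pd.Series(list(groups), index=X.index)
    group_names = sorted(set(labels.astype(str)))
    if len(group_names) < 2:
        raise ValueError("need >= 2 groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs >= 2 samples")

    X = X.astype(float)
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("features must be finite")

    variances = X.var(axis=0, ddof=0)
    dropped = [str(c) for c in X.columns[variances == 0.0]]
    X = X.loc[:, variances > 0.0]

    direction: dict[str, int] = {}
    if len(group_names) == 2:
        m0 = X[labels.astype(str) == group_names[0]].mean()
        m1 = X[labels.astype(str) == group_names[1]].mean()
        direction = {str(c): int(np.sign(m0[c] - m1[c])) for c in X.columns}

    if X.shape[1] == 0:
        return GroupComparison(feature_set, group_names, 0.0, 1.0, direction,
                               dropped, "degenerate")

    Y = X.to_numpy()
    N, p = Y.shape
    g = len(group_names)
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for name in group_names:
        sub = Y[(labels.astype(str) == name).to_numpy()]
        mean = sub.mean(axis=0)
        d = (mean - grand)[:, None]
        H += len(sub) * (d @ d.T)
        centred = sub - mean
        E += centred.T @ centred

    T = H + E
    # Pillai's trace: tr(H (H+E)^-1); singular T or E means no valid
    # multivariate test at this sample size
    try:
        if np.linalg.matrix_rank(E) < p:
            raise np.linalg.LinAlgError("singular within-group scatter")
        V = float(np.trace(H @ np.linalg.inv(T)))
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular within-group covariance; falling back to feature-wise "
            "univariate tests", RuntimeWarning, stacklevel=2)
        pvals = []
        fstats = []
        for j in range(p):
            samples = [Y[(labels.astype(str) == name).to_numpy(), j]
                       for name in group_names]
            res = sps.f_oneway(*samples)
            fstats.append(float(res.statistic))
            pvals.append(float(res.pvalue))
        p_combined = min(1.0, float(np.nanmin(pvals)) * p)
        return GroupComparison(feature_set, group_names, float(np.nanmax(fstats)),
                               p_combined, direction, dropped, "univariate_fallback")

    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    n = (N - g - p - 1) / 2.0
    if V <= 1e-14:
        return GroupComparison(feature_set, group_names, 0.0, 1.0, direction,
                               dropped, "pillai")
    F, df1, df2 = _pillai_f(V, s, m, n)
    if df2 <= 0 or not np.isfinite(F):
        p_value = 0.0 if not np.isfinite(F) else 1.0
    else:
        p_value = float(sps.f.sf(F, df1, df2))
    return GroupComparison(feature_set, group_names, V, p_value, direction,
                           dropped, "pillai")


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def composition_table(
    meta: pd.DataFrame,
    level: str = "subset",
    sample_col: str = "sample_id",
    denominator: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Per-sample proportions of cell categories.

    `level` names the metadata column holding the category. With a
    `denominator` mapping (e.g. lineage -> its subsets), proportions are
    computed within each denominator block; otherwise over all cells of
    the sample (CD45 denominator). Categories absent from a sample appear
    as 0 so every sample has the same feature vector; proportions sum to
    1 within each denominator block per sample.
    """
    categories = sorted(set(meta[level].astype(str)))
    counts = (
        meta.groupby([sample_col, level]).size().unstack(fill_value=0)
        .reindex(columns=categories, fill_value=0)
    )
    if denominator is None:
        props = counts.div(counts.sum(axis=1), axis=0)
    else:
        props = counts.astype(float)
        for _, block in denominator.items():
            cols = [c for c in block if c in props.columns]
            if not cols:
                continue
            totals = counts[cols].sum(axis=1).replace(0, np.nan)
            props[cols] = counts[cols].div(totals, axis=0).fillna(0.0)
    props.index.name = sample_col
    return props.sort_index()
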