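"""Cohort-level screening and classification of vascular parameters.

Given a tidy table of one parameter vector per tumor with a group
label, this module provides the three analyses used to judge a
parameter's discriminative power between tumor models: a one-way ANOVA
with Bonferroni-corrected pairwise post-hoc comparisons (p < 0.05
significant; Brown–Forsythe and Shapiro–Wilk assumption checks are
reported but never gate the computation), an exhaustive leave-one-out
nearest-neighbor classification summarized as a confusion matrix, and
the Pearson correlation matrix between parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "ConfusionMatrix",
    "anova_bonferroni",
    "nn_loocv_confusion",
    "correlation_matrix",
]


@dataclass
class AnovaResult:
    parameter: str
    omnibus_f: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, t, p_raw, p_bonferroni
    assumption_checks: dict[str, float] = field(default_factory=dict)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["p_bonferroni"] < alpha]
        return list(zip(sig["group_a"], sig["group_b"]))


@dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray  # (k, k), rows actual, cols predicted

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def anova_bonferroni(
    table: pd.DataFrame, parameter: str, group_col: str = "group"
) -> AnovaResult:
    """One-way ANOVA plus Bonferroni-adjusted pairwise post-hoc tests.

    Pairwise comparisons use two-sample t statistics with the pooled
    within-group variance of *all* groups (the classical post-hoc
    construction, df = N − k); each raw p is multiplied by the number
    of pairs and capped at 1.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [table.loc[table[group_col] == g, parameter].to_numpy(float) for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least two observations per group")
    if all(np.allclose(s, s.mean()) for s in samples):
        raise ValueError("zero within-group variance in every group: ANOVA degenerate")

    f_stat, p_omni = sps.f_oneway(*samples)

    n_total = sum(len(s) for s in samples)
    k = len(samples)
    df_within = n_total - k
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    ms_within = ss_within / df_within

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    rows = []
    for i, j in pairs:
        a, b = samples[i], samples[j]
        se = np.sqrt(ms_within * (1.0 / len(a) + 1.0 / len(b)))
        t = (a.mean() - b.mean()) / se
        p_raw = 2.0 * sps.t.sf(abs(t), df_within)
        rows.append(
            {
                "group_a": groups[i],
                "group_b": groups[j],
                "t": float(t),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, len(pairs) * p_raw)),
            }
        )

    checks: dict[str, float] = {}
    try:
        checks["brown_forsythe_p"] = float(sps.levene(*samples, center="median").pvalue)
    except ValueError:
        checks["brown_forsythe_p"] = float("nan")
    sw_ps = []
    for s in samples:
        if len(s) >= 3 and s.std() > 0:
            sw_ps.append(float(sps.shapiro(s).pvalue))
    checks["shapiro_wilk_min_p"] = min(sw_ps) if sw_ps else float("nan")

    return AnovaResult(
        parameter=parameter,
        omnibus_f=float(f_stat),
        omnibus_p=float(p_omni),
        pairwise=pd.DataFrame(rows),
        assumption_checks=checks,
    )


def nn_loocv_confusion(
    table: pd.DataFrame,
    parameters: list[str] | str,
    group_col: str = "group",
    standardize: bool = True,
) -> ConfusionMatrix:
    """Exhaustive leave-one-out nearest-neighbor classification.

    Each tumor is assigned the group of its nearest neighbor (Euclidean
    distance on z-scored parameter columns) among all *other* tumors.
    Distance ties are broken toward the smallest row index, so the
    result is deterministic and independent of row order up to the
    stated tie rule.
    """
    if isinstance(parameters, str):
        parameters = [parameters]
    labels = sorted(table[group_col].unique())
    if any((table[group_col] == g).sum() < 2 for g in labels):
        raise ValueError("need at least two tumors per group")
    x = table[parameters].to_numpy(float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    y = table[group_col].to_numpy()
    n = len(table)
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    idx = {g: i for i, g in enumerate(labels)}
    order = np.argsort(table.index.to_numpy())  # smallest tumor index wins ties
    for i in range(n):
        best_d, best_j = np.inf, -1
        for j in order:
            if j == i:
                continue
            d = float(np.linalg.norm(x[i] - x[j]))
            if d < best_d - 1e-12:
                best_d, best_j = d, j
        counts[idx[y[i]], idx[y[best_j]]] += 1
    return ConfusionMatrix(labels=list(labels), counts=counts)


def correlation_matrix(
    table: pd.DataFrame, parameters: list[str]
) -> pd.DataFrame:
    """Pairwise Pearson r between parameters; NaN for zero-variance columns."""
    if len(table) < 3:
        raise ValueError("need at least three rows for correlations")
    sub = table[parameters].astype(float)
    return sub.corr(method="pearson")
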