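"""Cohort-contrast statistics: per-coupling and network-metric comparisons.

Patients and controls are compared coupling-by-coupling with two-sample
Wilcoxon rank-sum tests corrected by Benjamini–Hochberg FDR (alpha = 0.05),
with the median difference med(groupA) - med(groupB) recording the effect
direction.  Network-metric triads (mean strength, global and local
efficiency, per subject and band) are compared with rank-sum tests under
Bonferroni correction across the tested family.  All comparisons are
restricted to the common good-sensor set across subjects.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def common_good_sensors(channel_lists: list[list[str]]) -> list[str]:
    """Order-stable intersection of per-subject good-channel lists.

    The order of the first subject's montage is preserved; an empty
    intersection raises.
    """
    if not channel_lists:
        raise ValueError("need at least one subject")
    common = set(channel_lists[0])
    for labels in channel_lists[1:]:
        common &= set(labels)
    if not common:
        raise ValueError("no sensor is good in all subjects")
    return [ch for ch in channel_lists[0] if ch in common]


def rank_sum_test(a: np.ndarray, b: np.ndarray,
                  alternative: str = "two-sided") -> tuple[float, float]:
    """Generic two-group Wilcoxon rank-sum test (one- or two-tailed)."""
    res = stats.ranksums(np.asarray(a), np.asarray(b), alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupContrast:
    """Per-feature rank-sum contrast after multiple-testing correction."""

    p_values: np.ndarray
    p_adjusted: np.ndarray
    median_diff: np.ndarray
    mask: np.ndarray
    alpha: float
    method: str


def compare_couplings(group_a: np.ndarray, group_b: np.ndarray,
                      alpha: float = 0.05) -> GroupContrast:
    """Coupling-wise rank-sum tests with Benjamini–Hochberg FDR control.

    Inputs are subject-averaged vec(W) patterns, (n_subjects, n_pairs); the
    median-difference sign encodes direction (positive = group A higher).
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the coupling set")
    p = stats.ranksums(a, b, axis=0).pvalue
    p = np.atleast_1d(np.asarray(p, float))
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return GroupContrast(p_values=p, p_adjusted=p_adj,
                         median_diff=np.median(a, axis=0) - np.median(b, axis=0),
                         mask=reject, alpha=alpha, method="fdr_bh")


def compare_network_metrics(group_a: pd.DataFrame, group_b: pd.DataFrame,
                            alpha: float = 0.01) -> pd.DataFrame:
    """Metric x band rank-sum comparisons, Bonferroni-corrected.

    Inputs are per-subject tables (one row per subject) whose columns span
    the tested family — e.g. a (metric, band) MultiIndex or flat
    "metric/band" names; the Bonferroni family is the full column set.
    """
    if list(group_a.columns) != list(group_b.columns):
        raise ValueError("groups must share the same metric/band columns")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for col in group_a.columns:
        stat, p = rank_sum_test(group_a[col].to_numpy(), group_b[col].to_numpy())
        rows.append({"measure": col, "statistic": stat, "p_value": p,
                     "median_diff": float(np.median(group_a[col])
                                          - np.median(group_b[col]))})
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha,
                                        method="bonferroni")
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out
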