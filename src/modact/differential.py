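"""Differential module activity between two sample groups.

Per module, a two-sided Wilcoxon rank-sum (Mann-Whitney) test compares
the activity distributions of the two groups; p-values are adjusted
across modules with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .expression import Design
from .propagation import ActivityMatrix

__all__ = ["DifferentialRow", "compare_conditions"]

EXACT_MAX_N = 8  # exact enumeration when both groups are at most this size and untied


@dataclass
class DifferentialRow:
    module_id: str
    mean_group1: float
    mean_group2: float
    statistic: float
    p_value: float
    fdr_p: float
    direction: str  # group2 relative to group1
    significant: bool
    zero_difference: bool = False


def _rank_sum_test(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small untied samples, else
    normal approximation with tie correction."""
    pooled = np.concatenate([g1, g2])
    if np.all(pooled == pooled[0]):
        return float(len(g1) * len(g2) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(g1) <= EXACT_MAX_N and len(g2) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.statistic), min(float(res.pvalue), 1.0)


def compare_conditions(
    act: ActivityMatrix,
    design: Design,
    group1: str,
    group2: str,
    alpha: float = 0.05,
    direction_by: str = "mean",
) -> list[DifferentialRow]:
    """Test every module for a shift in activity from group1 to group2.

    Returns rows sorted by FDR-adjusted p ascending; ``direction`` is
    "up" when group2 exceeds group1 (by mean, or median with
    ``direction_by="median"``).
    """
    for label in (group1, group2):
        if label not in design.classes:
            raise DataError(f"unknown class label {label!r}; design has {design.classes}")
    in_act = set(act.samples)
    s1 = [s for s in design.samples_of(group1) if s in in_act]
    s2 = [s for s in design.samples_of(group2) if s in in_act]
    if len(s1) < 2 or len(s2) < 2:
        raise DataError(
            f"need >=2 samples per group in the activity matrix "
            f"(got {len(s1)} for {group1!r}, {len(s2)} for {group2!r})"
        )
    center = np.mean if direction_by == "mean" else np.median
    raw: list[tuple[str, float, float, float, float]] = []
    for module_id in act.modules:
        g1 = act.data.loc[module_id, s1].to_numpy(dtype=float)
        g2 = act.data.loc[module_id, s2].to_numpy(dtype=float)
        statistic, p = _rank_sum_test(g1, g2)
        raw.append((module_id, float(np.mean(g1)), float(np.mean(g2)),
                    statistic, p, float(center(g2) - center(g1))))
    pvals = np.array([r[4] for r in raw])
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    rows = []
    for (module_id, m1, m2, statistic, p, diff), q in zip(raw, fdr):
        rows.append(
            DifferentialRow(
                module_id=module_id,
                mean_group1=m1,
                mean_group2=m2,
                statistic=statistic,
                p_value=p,
                fdr_p=float(q),
                direction="up" if diff >= 0 else "down",
                significant=bool(q < alpha),
                zero_difference=bool(diff == 0),
            )
        )
    rows.sort(key=lambda r: (r.fdr_p, r.p_value, r.module_id))
    return rows
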