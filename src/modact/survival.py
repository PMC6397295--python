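"""Survival association of module activities.

For each module, samples in the upper and lower activity percentiles
(20% by default) form two groups whose Kaplan-Meier curves are compared
with the two-group log-rank test; p-values are BH-adjusted across
modules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .propagation import ActivityMatrix

__all__ = [
    "SurvivalRecord",
    "SurvivalResultRow",
    "read_survival",
    "module_survival_association",
    "km_curve",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    sample: str
    time: float
    event: int  # 1 = event observed, 0 = censored

    def __post_init__(self):
        if self.time < 0:
            raise DataError(f"sample {self.sample!r}: negative survival time {self.time}")
        if self.event not in (0, 1):
            raise DataError(f"sample {self.sample!r}: event must be 0 or 1, got {self.event}")


@dataclass
class SurvivalResultRow:
    module_id: str
    chi_square: float
    p_value: float
    fdr_p: float
    n_high: int
    n_low: int


def read_survival(path) -> list[SurvivalRecord]:
    """TSV with header: sample<TAB>time<TAB>event."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise DataError(f"{path}: expected 3 columns (sample, time, event)")
    records = []
    seen = set()
    for _, row in df.iterrows():
        sample = str(row.iloc[0])
        if sample in seen:
            raise DataError(f"{path}: duplicate sample id {sample!r}")
        seen.add(sample)
        records.append(SurvivalRecord(sample=sample, time=float(row.iloc[1]), event=int(row.iloc[2])))
    return records


def km_curve(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate as step-function arrays.

    Returns ``(times, survival)`` starting at (0, 1); the curve is
    non-increasing and handles right-censoring.
    """
    if not records:
        raise DataError("km_curve requires at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.time for r in records],
        event_observed=[r.event for r in records],
    )
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times.size == 0 or times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    return times, surv


def _extreme_groups(
    activities: pd.Series, group_size: int
) -> tuple[list[str], list[str]]:
    """Top/bottom ``group_size`` samples by activity; boundary ties broken
    by sample id (stable sort on (activity, sample id))."""
    ordered = sorted(activities.index, key=lambda s: (activities[s], s))
    low = ordered[:group_size]
    high = ordered[-group_size:]
    return high, low


def module_survival_association(
    act: ActivityMatrix,
    surv: list[SurvivalRecord],
    percentile: float = 0.20,
) -> list[SurvivalResultRow]:
    """Log-rank comparison of high- vs low-activity extremes per module.

    Group size is ceil(percentile * n) over the samples that have both
    activity and survival data; the two groups must not overlap.
    """
    if not (0 < percentile <= 0.5):
        raise DataError(f"percentile must be in (0, 0.5], got {percentile}")
    by_sample = {r.sample: r for r in surv}
    shared = [s for s in act.samples if s in by_sample]
    dropped = len(act.samples) - len(shared)
    if dropped:
        log.info("dropping %d sample(s) without survival records", dropped)
    n = len(shared)
    g = math.ceil(percentile * n)
    if g < 1 or 2 * g > n:
        raise DataError(
            f"need at least 2*ceil(percentile*n) = {2 * g} samples with activity and survival, got {n}"
        )
    raw = []
    for module_id in act.modules:
        activities = act.data.loc[module_id, shared]
        high, low = _extreme_groups(activities, g)
        if set(high) & set(low):
            raise DataError(f"module {module_id}: high/low percentile groups overlap")
        res = logrank_test(
            [by_sample[s].time for s in high],
            [by_sample[s].time for s in low],
            event_observed_A=[by_sample[s].event for s in high],
            event_observed_B=[by_sample[s].event for s in low],
        )
        chi2 = float(res.test_statistic)
        p = float(res.p_value)
        if not (np.isfinite(chi2) and np.isfinite(p)):  # degenerate: no events or zero variance
            chi2, p = 0.0, 1.0
        raw.append((module_id, chi2, min(p, 1.0), len(high), len(low)))
    pvals = np.array([r[2] for r in raw])
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        SurvivalResultRow(module_id=m, chi_square=c, p_value=p, fdr_p=float(q), n_high=nh, n_low=nl)
        for (m, c, p, nh, nl), q in zip(raw, fdr)
    ]
    rows.sort(key=lambda r: (r.fdr_p, r.p_value, r.module_id))
    return rows
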