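"""MEP/behaviour preprocessing and the three subject-level ratio metrics.

The trial-level exclusion cascade removes stimulated trials with out-of-range
MEP amplitudes (outside 0.2--9 mV), incorrect, premature (<150 ms) or slow
(>800 ms) responses, and trials with precontraction above 0.4 mV; an
iterative two-sided Grubbs outlier test is then applied per condition.
Subject-level metrics are

    switch PP/SP ratio   = median(PP switch MEPs) / median(SP switch MEPs)
    switch M1 inhibition = median(SP switch MEPs) / median(SP stay MEPs)
    switch RT cost       = mean(switch RTs) / mean(stay RTs)

Subjects with fewer than nine retained MEPs in any of the four stimulation
conditions are flagged excluded. A Wilcoxon matched-pairs test with a
Hodges--Lehmann estimate quantifies the cohort-level switch-vs-stay
suppression of single-pulse MEPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import FilterThresholds

#: order in which exclusion reasons are attributed in the FilterReport;
#: the retained set itself is order-independent.
EXCLUSION_REASONS = (
    "small_mep",
    "large_mep",
    "incorrect",
    "premature",
    "slow",
    "precontraction",
)

CONDITIONS = (("stay", "SP"), ("switch", "SP"), ("stay", "PP"), ("switch", "PP"))


class EmptyInputError(ValueError):
    pass


@dataclass
class FilterReport:
    counts: dict[str, int]
    retained: int
    total: int

    @property
    def rates(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "retained": self.retained,
            "total": self.total,
            "rates": self.rates,
        }


@dataclass
class SubjectPhysiology:
    subject: str
    switch_pp_sp_ratio: float | None
    switch_m1_inhibition: float | None
    switch_rt_cost: float | None
    sp_switch_median: float | None
    sp_stay_median: float | None
    n_meps_per_condition: dict[str, int] = field(default_factory=dict)
    included: bool = True


def _exclusion_reason(df: pd.DataFrame, thresholds: FilterThresholds) -> pd.Series:
    """First matching exclusion rule per trial, '' if retained.

    MEP-amplitude rules apply only to stimulated trials (condition SP/PP with
    a recorded amplitude); behavioural and precontraction rules to all trials.
    """
    reason = pd.Series("", index=df.index, dtype=object)
    stimulated = df["condition"].isin(["SP", "PP"]) & df["mep_mv"].notna()
    rules = [
        ("small_mep", stimulated & (df["mep_mv"] < thresholds.min_mep_mv)),
        ("large_mep", stimulated & (df["mep_mv"] > thresholds.max_mep_mv)),
        ("incorrect", ~df["correct"].astype(bool)),
        ("premature", df["rt_ms"].notna() & (df["rt_ms"] < thresholds.min_rt_ms)),
        ("slow", df["rt_ms"].notna() & (df["rt_ms"] > thresholds.max_rt_ms)),
        ("precontraction", df["precontraction_mv"] > thresholds.max_precontraction_mv),
    ]
    for name, hit in rules:
        fresh = hit & (reason == "")
        reason[fresh] = name
    return reason


def filter_trials(
    trials: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the trial-level exclusion cascade.

    Returns the retained trials (original order preserved) and a report
    attributing each excluded trial to the first matching rule.
    """
    if len(trials) == 0:
        raise EmptyInputError("filter_trials requires at least one trial")
    thresholds = thresholds or FilterThresholds()
    reason = _exclusion_reason(trials, thresholds)
    counts = {name: int((reason == name).sum()) for name in EXCLUSION_REASONS}
    retained = trials.loc[reason == ""].copy()
    report = FilterReport(counts=counts, retained=len(retained), total=len(trials))
    return retained, report


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outlier_removal(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iterative two-sided Grubbs outlier removal.

    Repeatedly tests the most extreme standardized deviation
    ``max |x - mean| / sd`` against the critical value built from the
    Student-t quantile, removing one value per iteration while significant.
    Order of the retained values is preserved. Inputs with fewer than three
    values, or zero variance, are returned unchanged (with a warning for the
    short-input case).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    values = np.asarray(values, dtype=float)
    removed: list[int] = []
    keep = np.arange(len(values))
    if len(values) < 3:
        warnings.warn("Grubbs test requires at least 3 values; input returned unchanged")
        return values.copy(), removed
    while len(keep) >= 3:
        x = values[keep]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical_value(len(x), alpha):
            removed.append(int(keep[i]))
            keep = np.delete(keep, i)
        else:
            break
    return values[np.sort(keep)], removed


def _median_or_none(values: np.ndarray) -> float | None:
    return float(np.median(values)) if len(values) else None


def _mep(trials: pd.DataFrame, trial_type: str, condition: str) -> np.ndarray:
    sel = (trials["trial_type"] == trial_type) & (trials["condition"] == condition)
    return trials.loc[sel & trials["mep_mv"].notna(), "mep_mv"].to_numpy(dtype=float)


def compute_switch_pp_sp_ratio(trials: pd.DataFrame) -> float | None:
    """Median PP-switch MEP over median SP-switch MEP; stay trials never enter."""
    pp = _median_or_none(_mep(trials, "switch", "PP"))
    sp = _median_or_none(_mep(trials, "switch", "SP"))
    if pp is None or sp is None:
        return None
    return pp / sp


def compute_switch_m1_inhibition(trials: pd.DataFrame) -> float | None:
    """Median SP-switch MEP over median SP-stay MEP."""
    sw = _median_or_none(_mep(trials, "switch", "SP"))
    st = _median_or_none(_mep(trials, "stay", "SP"))
    if sw is None or st is None:
        return None
    return sw / st


def compute_switch_rt_cost(trials: pd.DataFrame) -> float | None:
    """Mean switch RT over mean stay RT (correct, in-window trials only)."""
    rts = trials.loc[trials["rt_ms"].notna()]
    sw = rts.loc[rts["trial_type"] == "switch", "rt_ms"].to_numpy(dtype=float)
    st = rts.loc[rts["trial_type"] == "stay", "rt_ms"].to_numpy(dtype=float)
    if len(sw) == 0 or len(st) == 0:
        return None
    return float(sw.mean() / st.mean())


def preprocess_subject(
    trials: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    grubbs_alpha: float = 0.05,
    min_count: int = 9,
) -> tuple[SubjectPhysiology, FilterReport]:
    """Full per-subject cascade: rule filter, per-condition Grubbs, metrics."""
    subject = str(trials["subject"].iloc[0]) if len(trials) else "?"
    retained, report = filter_trials(trials, thresholds)

    # Grubbs per stimulation condition, one value at a time
    grubbs_removed = 0
    keep_idx: list[np.ndarray] = []
    for trial_type, condition in CONDITIONS:
        sel = (
            (retained["trial_type"] == trial_type)
            & (retained["condition"] == condition)
            & retained["mep_mv"].notna()
        )
        idx = retained.index[sel].to_numpy()
        _, removed = grubbs_outlier_removal(
            retained.loc[idx, "mep_mv"].to_numpy(dtype=float), grubbs_alpha
        )
        grubbs_removed += len(removed)
        keep_idx.append(np.delete(idx, removed))
    unstimulated = retained.index[~retained["condition"].isin(["SP", "PP"])].to_numpy()
    kept = np.sort(np.concatenate(keep_idx + [unstimulated]))
    clean = retained.loc[kept]

    report.counts["grubbs"] = grubbs_removed
    report.retained = len(clean)

    counts = {
        f"{tt}_{c}": int(len(_mep(clean, tt, c))) for tt, c in CONDITIONS
    }
    phys = SubjectPhysiology(
        subject=subject,
        switch_pp_sp_ratio=compute_switch_pp_sp_ratio(clean),
        switch_m1_inhibition=compute_switch_m1_inhibition(clean),
        switch_rt_cost=compute_switch_rt_cost(clean),
        sp_switch_median=_median_or_none(_mep(clean, "switch", "SP")),
        sp_stay_median=_median_or_none(_mep(clean, "stay", "SP")),
        n_meps_per_condition=counts,
        included=all(v >= min_count for v in counts.values()),
    )
    return phys, report


def exclude_low_count_subjects(
    cohort: list[SubjectPhysiology], min_count: int = 9
) -> list[SubjectPhysiology]:
    """Flag subjects with fewer than ``min_count`` MEPs in any condition.

    Excluded subjects stay in the output with ``included=False``.
    """
    for phys in cohort:
        phys.included = all(
            v >= min_count for v in phys.n_meps_per_condition.values()
        )
    return cohort


def _hodges_lehmann(diff: np.ndarray, conf: float = 0.95):
    """Hodges--Lehmann estimate and distribution-free CI from Walsh averages.

    The CI rank uses the normal approximation to the signed-rank null
    distribution.
    """
    n = len(diff)
    walsh = np.sort(
        np.add.outer(diff, diff)[np.triu_indices(n)] / 2.0
    )
    estimate = float(np.median(walsh))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    mean_w = n * (n + 1) / 4.0
    sd_w = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    k = int(np.floor(mean_w - z * sd_w))
    k = max(k, 0)
    n_w = len(walsh)
    low = float(walsh[k]) if k < n_w else float(walsh[0])
    high = float(walsh[n_w - 1 - k]) if k < n_w else float(walsh[-1])
    return estimate, (low, high)


def wilcoxon_switch_vs_stay(cohort: list[SubjectPhysiology], conf: float = 0.95):
    """Wilcoxon matched-pairs test of SP-switch vs SP-stay condition medians.

    Uses included subjects with both medians available. Returns the
    Hodges--Lehmann estimate of the paired difference, its distribution-free
    CI, and the two-sided signed-rank p-value.
    """
    diffs = np.array(
        [
            p.sp_switch_median - p.sp_stay_median
            for p in cohort
            if p.included
            and p.sp_switch_median is not None
            and p.sp_stay_median is not None
        ]
    )
    if len(diffs) < 6:
        raise ValueError(f"need at least 6 included subjects, got {len(diffs)}")
    if np.all(diffs == 0):
        return 0.0, (0.0, 0.0), 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(diffs, zero_method="wilcox", method="auto")
    estimate, ci = _hodges_lehmann(diffs, conf)
    return estimate, ci, float(res.pvalue)


def cohort_physiology(
    trial_tables: dict[str, pd.DataFrame],
    thresholds: FilterThresholds | None = None,
    grubbs_alpha: float = 0.05,
    min_count: int = 9,
) -> tuple[list[SubjectPhysiology], dict[str, FilterReport]]:
    """Run the per-subject cascade over a cohort of trial tables."""
    cohort, reports = [], {}
    for sid, table in trial_tables.items():
        phys, report = preprocess_subject(table, thresholds, grubbs_alpha, min_count)
        cohort.append(phys)
        reports[sid] = report
    return cohort, reports


def physiology_frame(cohort: list[SubjectPhysiology]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {
            "subject": p.subject,
            "switch_pp_sp_ratio": p.switch_pp_sp_ratio,
            "switch_m1_inhibition": p.switch_m1_inhibition,
            "switch_rt_cost": p.switch_rt_cost,
            "sp_switch_median": p.sp_switch_median,
            "sp_stay_median": p.sp_stay_median,
            "included": p.included,
        }
        row.update({f"n_{k}": v for k, v in p.n_meps_per_condition.items()})
        rows.append(row)
    return pd.DataFrame(rows)
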