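"""Antidepressant treatment episodes and intensification trajectories.

A treatment episode is a maximal run of prescription coverage: each fill
covers ``[date, date + days_supplied)`` and intervals whose gap does not
exceed a grace period merge.  Trajectory classification ranks each case's most
intensive observed step: no antidepressant < monotherapy < switch (a second
antidepressant class without sustained concurrency) < combination or
augmentation (two classes overlapping at least ``overlap_days``, or an
augmentation agent dispensed during antidepressant coverage) < ECT.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .codes import CodeMap
from .registry import Cohort, first_diagnosis_table

__all__ = ["build_episodes", "classify_trajectories", "trajectory_summary",
           "STEP_ORDER"]

DAYS_PER_YEAR = 365.25
ANTIDEPRESSANT_CLASSES = ("SSRI", "SNRI", "TCA", "other_antidepressant")
STEP_ORDER = ("no_antidepressant", "monotherapy", "switch",
              "combination_or_augmentation", "ect")
_STEP_RANK = {s: i for i, s in enumerate(STEP_ORDER)}


def build_episodes(fills: pd.DataFrame, grace_days: float = 56.0
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge fills into per-person treatment episodes.

    Returns ``(episodes, summaries)``.  Episodes have person_id, start, end
    (decimal years, half-open), drug classes involved and fill count;
    summaries have per-person total months covered, episode count and number
    of distinct drug classes.  Order-independent: fills are sorted first.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be >= 0")
    if not len(fills):
        empty_e = pd.DataFrame(columns=["person_id", "start", "end",
                                        "drug_classes", "n_fills"])
        empty_s = pd.DataFrame(columns=["person_id", "total_months",
                                        "n_episodes", "n_distinct_drugs"])
        return empty_e, empty_s
    grace = grace_days / DAYS_PER_YEAR
    f = fills.sort_values(["person_id", "date"], kind="mergesort").reset_index(drop=True)
    start = f["date"].to_numpy(dtype=float)
    end = start + f["days_supplied"].to_numpy(dtype=float) / DAYS_PER_YEAR
    pid = f["person_id"].to_numpy()

    # running coverage end within person, then break where the gap exceeds grace
    cur_end = -np.inf
    cur_pid = None
    eid = -1
    episode_id = np.empty(len(f), dtype=int)
    for k in range(len(f)):
        if pid[k] != cur_pid or start[k] - cur_end > grace:
            eid += 1
            cur_pid = pid[k]
            cur_end = end[k]
        else:
            cur_end = max(cur_end, end[k])
        episode_id[k] = eid

    f = f.assign(_eid=episode_id, _end=end)
    grouped = f.groupby("_eid")
    episodes = pd.DataFrame({
        "person_id": grouped["person_id"].first(),
        "start": grouped["date"].min(),
        "end": grouped["_end"].max(),
        "drug_classes": grouped["drug_class"].agg(lambda s: tuple(sorted(set(s)))),
        "n_fills": grouped.size(),
    }).reset_index(drop=True)

    dur_months = (episodes["end"] - episodes["start"]) * 12.0
    summaries = episodes.assign(_months=dur_months).groupby("person_id").agg(
        total_months=("_months", "sum"), n_episodes=("start", "size"))
    ndrugs = f.groupby("person_id")["drug_class"].nunique().rename("n_distinct_drugs")
    summaries = summaries.join(ndrugs).reset_index()
    return episodes, summaries


def _class_intervals(dates: np.ndarray, days: np.ndarray, grace: float):
    """Merged coverage intervals for one drug class (inputs pre-sorted)."""
    out = []
    s = e = None
    for d, ds in zip(dates, days):
        d_end = d + ds / DAYS_PER_YEAR
        if s is None or d - e > grace:
            if s is not None:
                out.append((s, e))
            s, e = d, d_end
        else:
            e = max(e, d_end)
    if s is not None:
        out.append((s, e))
    return out


def classify_trajectories(cohort: Cohort, fills: pd.DataFrame,
                          diagnoses: Optional[pd.DataFrame] = None,
                          code_map: Optional[CodeMap] = None,
                          overlap_days: float = 30.0,
                          grace_days: float = 56.0) -> pd.DataFrame:
    """Highest treatment-intensification step per MDD case.

    Returns a frame with person_id, step, time_to_step (years from first MDD
    diagnosis, floored at 0; NaN for the no-antidepressant class).  Every case
    appears exactly once, so the classes partition the case set.
    """
    overlap = overlap_days / DAYS_PER_YEAR
    grace = grace_days / DAYS_PER_YEAR
    cases = cohort.cases
    first_mdd = cases["first_mdd_date"]

    ect_date = pd.Series(dtype=float)
    if diagnoses is not None and code_map is not None and "ect" in code_map.disorders():
        ect_date = first_diagnosis_table(diagnoses, "ect", code_map)

    f = fills[fills["person_id"].isin(cases.index)]
    f = f.sort_values(["person_id", "date"], kind="mergesort")
    by_person = dict(tuple(f.groupby("person_id")))

    rows = []
    for pid, fdx in first_mdd.items():
        step, when = "no_antidepressant", np.nan
        pf = by_person.get(pid)
        if pf is not None and len(pf):
            ad = pf[pf["drug_class"].isin(ANTIDEPRESSANT_CLASSES)]
            aug = pf[pf["drug_class"] == "augmentation_agent"]
            if len(ad):
                step, when = "monotherapy", float(ad["date"].iloc[0])
                classes = ad["drug_class"].to_numpy()
                if len(set(classes)) >= 2:
                    second_idx = np.flatnonzero(classes != classes[0])[0]
                    step, when = "switch", float(ad["date"].iloc[second_idx])
                intervals = {
                    c: _class_intervals(
                        ad.loc[ad["drug_class"] == c, "date"].to_numpy(float),
                        ad.loc[ad["drug_class"] == c, "days_supplied"].to_numpy(float),
                        grace)
                    for c in set(classes)}
                combo_when = np.inf
                cls = sorted(intervals)
                for i, c1 in enumerate(cls):
                    for c2 in cls[i + 1:]:
                        for s1, e1 in intervals[c1]:
                            for s2, e2 in intervals[c2]:
                                ov = min(e1, e2) - max(s1, s2)
                                # tolerance guards exact-threshold overlaps
                                # against date-arithmetic rounding
                                if ov >= overlap - 1e-9:
                                    combo_when = min(combo_when, max(s1, s2) + overlap)
                if len(aug):
                    all_iv = [iv for ivs in intervals.values() for iv in ivs]
                    for d in aug["date"].to_numpy(float):
                        if any(s <= d < e for s, e in all_iv):
                            combo_when = min(combo_when, d)
                            break
                if np.isfinite(combo_when):
                    step, when = "combination_or_augmentation", float(combo_when)
        ect_when = ect_date.get(pid, np.nan)
        if pd.notna(ect_when):
            step, when = "ect", float(ect_when)
        rows.append({"person_id": pid, "step": step,
                     "time_to_step": max(when - fdx, 0.0) if np.isfinite(when) else np.nan})
    out = pd.DataFrame(rows, columns=["person_id", "step", "time_to_step"])
    out["step"] = pd.Categorical(out["step"], categories=list(STEP_ORDER), ordered=True)
    return out


def trajectory_summary(traj: pd.DataFrame) -> pd.DataFrame:
    """Per-step share of cases and median/IQR time to the step."""
    n = len(traj)
    rows = []
    for step in STEP_ORDER:
        sub = traj[traj["step"] == step]
        t = sub["time_to_step"].dropna()
        q1, med, q3 = np.percentile(t, [25, 50, 75]) if len(t) else (np.nan,) * 3
        rows.append({"step": step, "n": len(sub),
                     "pct_of_cases": len(sub) / n * 100 if n else np.nan,
                     "median_years_to_step": med, "iqr_years": q3 - q1})
    return pd.DataFrame(rows)
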