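"""Cumulative incidence with censoring, prevalence/relative-risk summaries and
bidirectional comorbidity trajectories.

Both estimators (one-minus-Kaplan-Meier and Aalen-Johansen with death as a
competing risk) are computed from one shared risk-set table so that tie
handling (events processed before censorings), delayed entry (left truncation)
and the exact equality AJ = 1-KM in the absence of competing events are under
the package's control.  Pointwise bands use Greenwood-type plug-in variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .codes import CodeMap
from .registry import Cohort, first_diagnosis_table

__all__ = ["IncidenceCurve", "incidence_from_arrays", "cumulative_incidence",
           "lifetime_prevalence_and_rr", "comorbidity_trajectories",
           "prevalence_difference_test", "ChiSquareResult"]

DEFAULT_AGE_BANDS = ((10, 19), (20, 29), (30, 39), (40, 49))


@dataclass
class IncidenceCurve:
    """Age-indexed cumulative incidence with risk sets and a 95% band."""

    ages: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_risk: np.ndarray
    estimator: str
    stratum: str = ""

    def at(self, age: float) -> float:
        """Step-function value at ``age`` (last jump at or before it)."""
        idx = np.searchsorted(self.ages, age, side="right") - 1
        return float(self.estimate[idx]) if idx >= 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stratum": self.stratum, "age": self.ages, "estimate": self.estimate,
            "lo": self.lower, "hi": self.upper, "n_risk": self.n_risk,
            "estimator": self.estimator,
        })


def _risk_table(entry, time, status):
    """Unique event-time table: n at risk, events, competing events.

    Risk set at t counts subjects with ``entry < t <= time``; subjects censored
    exactly at t therefore remain in the risk set (events before censorings).
    """
    times = np.unique(time[status > 0])
    entry_sorted = np.sort(entry)
    time_sorted = np.sort(time)
    # at risk at t: entered strictly before t and not yet exited (time >= t)
    n = (np.searchsorted(entry_sorted, times, side="left")
         - np.searchsorted(time_sorted, times, side="left"))
    t1, c1 = np.unique(time[status == 1], return_counts=True)
    t2, c2 = np.unique(time[status == 2], return_counts=True)
    d1 = np.zeros(len(times), dtype=int)
    d2 = np.zeros(len(times), dtype=int)
    d1[np.searchsorted(times, t1)] = c1
    d2[np.searchsorted(times, t2)] = c2
    return times, n, d1, d2


def incidence_from_arrays(entry, exit_age, event_age=None, competing_age=None,
                          estimator: str = "aalen_johansen",
                          age_grid: Optional[np.ndarray] = None,
                          stratum: str = "") -> IncidenceCurve:
    """Cumulative incidence from per-person ages.

    Parameters are arrays over persons: ``entry``/``exit_age`` delimit the
    half-open observation window, ``event_age`` is the age at the event of
    interest (NaN when none) and ``competing_age`` the age at a competing
    terminal event (NaN when none).  Persons whose resolved time is not after
    entry are left-truncated out of the risk sets.
    """
    if estimator not in {"aalen_johansen", "one_minus_km"}:
        raise ValueError(f"unknown estimator {estimator!r}")
    entry = np.asarray(entry, dtype=float)
    exit_age = np.asarray(exit_age, dtype=float)
    if len(entry) == 0:
        raise ValueError("empty risk population")
    event_age = np.full_like(entry, np.nan) if event_age is None \
        else np.asarray(event_age, dtype=float)
    competing_age = np.full_like(entry, np.nan) if competing_age is None \
        else np.asarray(competing_age, dtype=float)

    ev = np.fmin(np.nan_to_num(event_age, nan=np.inf), np.inf)
    cp = np.nan_to_num(competing_age, nan=np.inf)
    time = np.fmin(np.fmin(ev, cp), exit_age)
    status = np.zeros(len(entry), dtype=int)
    status[(ev <= cp) & (ev <= exit_age) & np.isfinite(ev)] = 1
    status[(cp < ev) & (cp <= exit_age) & np.isfinite(cp)] = 2
    ok = time > entry          # left truncation
    entry, time, status = entry[ok], time[ok], status[ok]

    if age_grid is None:
        lo = float(np.floor(entry.min())) if len(entry) else 0.0
        hi = float(np.ceil(exit_age.max()))
        age_grid = np.arange(lo, hi + 1.0)
    age_grid = np.asarray(age_grid, dtype=float)

    times, n, d1, d2 = _risk_table(entry, time, status)
    if len(times) == 0 or not (status == 1).any():
        warnings.warn(f"all-censored stratum {stratum!r}: returning zero curve",
                      stacklevel=2)
        zero = np.zeros(len(age_grid))
        n_risk = (np.searchsorted(np.sort(entry), age_grid, side="right")
                  - np.searchsorted(np.sort(time), age_grid, side="right"))
        return IncidenceCurve(age_grid, zero, zero, zero, n_risk, estimator, stratum)

    with np.errstate(divide="ignore", invalid="ignore"):
        if estimator == "one_minus_km":
            surv = np.cumprod(1.0 - d1 / n)
            cif = 1.0 - surv
            gw = np.cumsum(np.where(n > d1, d1 / (n * (n - d1)), 0.0))
            var = surv**2 * gw
        else:
            d_all = d1 + d2
            surv_all = np.cumprod(1.0 - d_all / n)
            surv_prev = np.concatenate(([1.0], surv_all[:-1]))
            jumps = surv_prev * d1 / n
            cif = np.cumsum(jumps)
            # Greenwood-type plug-in variance on the sub-distribution jumps
            var = np.cumsum(surv_prev**2 * d1 * np.maximum(n - d1, 0) / n**3)

    idx = np.searchsorted(times, age_grid, side="right") - 1
    est = np.where(idx >= 0, cif[np.clip(idx, 0, None)], 0.0)
    v = np.where(idx >= 0, var[np.clip(idx, 0, None)], 0.0)
    half = 1.96 * np.sqrt(v)
    n_risk = (np.searchsorted(np.sort(entry), age_grid, side="right")
              - np.searchsorted(np.sort(time), age_grid, side="right"))
    return IncidenceCurve(age_grid, est, np.clip(est - half, 0.0, 1.0),
                          np.clip(est + half, 0.0, 1.0), n_risk, estimator, stratum)


def cumulative_incidence(cohort: Cohort, estimator: str = "aalen_johansen",
                         age_grid: Optional[np.ndarray] = None,
                         stratum: str = "all") -> IncidenceCurve:
    """Cumulative incidence of first MDD diagnosis in the cohort, death treated
    as a competing risk under the Aalen-Johansen default."""
    m = cohort.members
    if not len(m):
        raise ValueError("empty cohort")
    death_age = (m["death_year"] - (m["birth_year"] + 0.5)).to_numpy(dtype=float)
    if age_grid is None:
        age_grid = np.arange(np.floor(cohort.spec.min_diagnosis_age),
                             cohort.spec.age_cap + 1.0)
    return incidence_from_arrays(m["entry_age"].to_numpy(), m["exit_age"].to_numpy(),
                                 m["first_mdd_age"].to_numpy(), death_age,
                                 estimator=estimator, age_grid=age_grid,
                                 stratum=stratum)


def _age_band_labels(bands) -> list[str]:
    return [f"{lo}-{hi}" for lo, hi in bands]


def lifetime_prevalence_and_rr(cohort: Cohort, diagnoses: pd.DataFrame,
                               code_map: CodeMap,
                               disorders: Optional[Iterable[str]] = None,
                               age_bands=DEFAULT_AGE_BANDS):
    """Diagnosed proportions per disorder x sex x attained-age band, plus the
    female:male lifetime relative risk with a log-scale 95% CI per disorder.

    The age band is the member's attained age at end of follow-up (capped).
    """
    m = cohort.members
    if not set(m["sex"]) >= {"F", "M"}:
        raise ValueError("both sexes must be present for relative risks")
    if disorders is None:
        disorders = [d for d in code_map.disorders()
                     if d not in {"mdd_recurrent", "self_harm", "ect"}]
    attained = m["exit_age"].to_numpy()
    band = np.full(len(m), "", dtype=object)
    for lo, hi in age_bands:
        band[(attained >= lo) & (attained < hi + 1)] = f"{lo}-{hi}"

    rows, rr = [], {}
    for disorder in disorders:
        first = first_diagnosis_table(diagnoses, disorder, code_map)
        dx_date = m.index.map(first)
        diagnosed = pd.notna(dx_date) & (dx_date < m["exit_date"].to_numpy())
        for sex in ("F", "M"):
            sel = (m["sex"] == sex).to_numpy()
            for lab in _age_band_labels(age_bands):
                in_band = sel & (band == lab)
                pop = int(in_band.sum())
                cnt = int((diagnosed & in_band).sum())
                rows.append({"disorder": disorder, "sex": sex, "age_band": lab,
                             "diagnosed": cnt, "population": pop,
                             "proportion": cnt / pop if pop else np.nan})
        f, mle = (m["sex"] == "F").to_numpy(), (m["sex"] == "M").to_numpy()
        a, nf = int((diagnosed & f).sum()), int(f.sum())
        b, nm = int((diagnosed & mle).sum()), int(mle.sum())
        if a and b:
            est = (a / nf) / (b / nm)
            se = np.sqrt(1 / a - 1 / nf + 1 / b - 1 / nm)
            rr[disorder] = (est, est * np.exp(-1.96 * se), est * np.exp(1.96 * se))
        else:
            rr[disorder] = (np.nan, np.nan, np.nan)
    return pd.DataFrame(rows), rr


def comorbidity_trajectories(cohort: Cohort, diagnoses: pd.DataFrame,
                             code_map: CodeMap, index_disorder: str = "mdd",
                             other_disorders: Iterable[str] = (),
                             direction: str = "after",
                             estimator: str = "aalen_johansen",
                             age_grid: Optional[np.ndarray] = None
                             ) -> dict[str, IncidenceCurve]:
    """Cumulative incidence curves linking MDD and each comorbid disorder.

    ``direction="before"``: among persons with disorder D, incidence of the
    index disorder from D's onset.  ``direction="after"``: among index-disorder
    cases, incidence of D from the index onset.  The time axis is age; persons
    with the outcome before the index onset leave the risk set entirely.
    """
    if direction not in {"before", "after"}:
        raise ValueError("direction must be 'before' or 'after'")
    m = cohort.members
    birth = (m["birth_year"] + 0.5).to_numpy()
    death_age = (m["death_year"].to_numpy(dtype=float) - birth)
    if age_grid is None:
        age_grid = np.arange(np.floor(cohort.spec.min_diagnosis_age),
                             cohort.spec.age_cap + 1.0)

    out: dict[str, IncidenceCurve] = {}
    for other in other_disorders:
        if other == index_disorder:
            raise ValueError("index and outcome disorder must differ")
        other_age = (m.index.map(first_diagnosis_table(diagnoses, other, code_map))
                     .to_numpy(dtype=float) - birth)
        index_age = m["first_mdd_age"].to_numpy(dtype=float) \
            if index_disorder == "mdd" else \
            (m.index.map(first_diagnosis_table(diagnoses, index_disorder, code_map))
             .to_numpy(dtype=float) - birth)
        if direction == "before":
            cond_age, outcome_age = other_age, index_age
        else:
            cond_age, outcome_age = index_age, other_age
        has_cond = np.isfinite(np.nan_to_num(cond_age, nan=np.inf)) & ~np.isnan(cond_age)
        # outcome before (or at) the conditioning onset -> out of the risk set
        eligible = has_cond & ~(np.nan_to_num(outcome_age, nan=np.inf) <= cond_age)
        label = f"{index_disorder}_after_{other}" if direction == "before" \
            else f"{other}_after_{index_disorder}"
        if not eligible.any():
            warnings.warn(f"empty stratum for {label}", stacklevel=2)
            zeros = np.zeros(len(age_grid))
            out[other] = IncidenceCurve(np.asarray(age_grid, float), zeros, zeros,
                                        zeros, np.zeros(len(age_grid), int),
                                        estimator, label)
            continue
        entry = np.maximum(m["entry_age"].to_numpy()[eligible], cond_age[eligible])
        out[other] = incidence_from_arrays(
            entry, m["exit_age"].to_numpy()[eligible], outcome_age[eligible],
            death_age[eligible], estimator=estimator, age_grid=age_grid,
            stratum=label)
    return out


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float


def prevalence_difference_test(counts: Iterable[tuple[int, int]]) -> ChiSquareResult:
    """Pearson chi-squared for equality of proportions across k groups.

    ``counts`` is an iterable of ``(diagnosed, total)`` pairs, one per group.
    """
    table = []
    for diagnosed, total in counts:
        if total <= 0 or diagnosed < 0 or diagnosed > total:
            raise ValueError("need 0 <= diagnosed <= total and total > 0")
        table.append([diagnosed, total - diagnosed])
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any():
        return ChiSquareResult(0.0, len(table) - 1, 1.0)
    res = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))
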