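"""Clinical outcomes among MDD cases and cross-country comparison statistics.

Outcomes: recurrence (a recurrent-MDD code after first diagnosis), diagnostic
cross-over (a bipolar or schizophrenia-spectrum code more than a wash-out
period after first MDD; codes inside the wash-out window are treated as
diagnostic uncertainty and those persons leave the cross-over denominator),
self-harm, suicide and other-cause mortality before age 50.  All outcomes are
evaluated inside each member's follow-up window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .codes import CROSSOVER_DISORDERS, CodeMap
from .incidence import DEFAULT_AGE_BANDS
from .registry import Cohort, first_diagnosis_table

__all__ = ["clinical_outcomes", "cochran_q", "country_comparison",
           "treatment_contacts", "CochranQResult"]

OUTCOMES = ("recurrence", "crossover", "selfharm", "suicide", "other_mortality")
MORTALITY_AGE_CAP = 50.0


def _band_label(age: float, bands) -> str:
    for lo, hi in bands:
        if lo <= age < hi + 1:
            return f"{lo}-{hi}"
    return "other"


def clinical_outcomes(cohort: Cohort, diagnoses: pd.DataFrame, code_map: CodeMap,
                      washout_years: float = 1.0,
                      age_bands=DEFAULT_AGE_BANDS) -> pd.DataFrame:
    """Outcome rates among MDD cases, stratified by sex and age at first
    diagnosis, as a tidy frame (outcome, sex, age_band, numerator, denominator,
    proportion); "all" rows aggregate over strata.

    Cross-over wash-out: members whose first bipolar/schizophrenia-spectrum
    code falls within ``washout_years`` after (or at/before) first MDD are
    excluded from the cross-over denominator.
    """
    if washout_years < 0:
        raise ValueError("washout_years must be >= 0")
    cases = cohort.cases
    if not len(cases):
        raise ValueError("no MDD cases in cohort")
    first = cases["first_mdd_date"].to_numpy()
    exit_date = cases["exit_date"].to_numpy()
    birth = (cases["birth_year"] + 0.5).to_numpy()
    death_age = cases["death_year"].to_numpy(dtype=float) - birth

    rec_date = cases.index.map(
        first_diagnosis_table(diagnoses, "mdd_recurrent", code_map)).to_numpy(float)
    recurrence = np.isfinite(np.nan_to_num(rec_date, nan=np.inf)) \
        & (rec_date >= first) & (rec_date < exit_date) & ~np.isnan(rec_date)

    cross_dates = [cases.index.map(first_diagnosis_table(diagnoses, d, code_map))
                   .to_numpy(float) for d in CROSSOVER_DISORDERS]
    cross = np.fmin.reduce(cross_dates)
    has_cross = ~np.isnan(cross)
    in_washout = has_cross & (cross <= first + washout_years)
    crossover = has_cross & ~in_washout & (cross < exit_date)

    sh_date = cases.index.map(
        first_diagnosis_table(diagnoses, "self_harm", code_map)).to_numpy(float)
    selfharm = ~np.isnan(sh_date) & (sh_date >= first) & (sh_date < exit_date)

    suicide = cases["suicide_death"].to_numpy(dtype=bool) \
        & (death_age < MORTALITY_AGE_CAP)
    other_mortality = (cases["death_cause"] == "other").to_numpy() \
        & ~np.isnan(death_age) & (death_age < MORTALITY_AGE_CAP)

    events = {"recurrence": recurrence, "crossover": crossover,
              "selfharm": selfharm, "suicide": suicide,
              "other_mortality": other_mortality}
    in_denominator = {o: np.ones(len(cases), dtype=bool) for o in OUTCOMES}
    in_denominator["crossover"] = ~in_washout

    sex = cases["sex"].to_numpy()
    band = np.array([_band_label(a, age_bands)
                     for a in cases["first_mdd_age"].to_numpy()])
    rows = []
    strata = [("all", "all", np.ones(len(cases), dtype=bool))]
    for s in ("F", "M"):
        for lab in [f"{lo}-{hi}" for lo, hi in age_bands]:
            strata.append((s, lab, (sex == s) & (band == lab)))
    for outcome in OUTCOMES:
        for s, lab, mask in strata:
            den = mask & in_denominator[outcome]
            n_den = int(den.sum())
            n_num = int((events[outcome] & den).sum())
            rows.append({"outcome": outcome, "sex": s, "age_band": lab,
                         "numerator": n_num, "denominator": n_den,
                         "proportion": n_num / n_den if n_den else np.nan})
    return pd.DataFrame(rows)


@dataclass
class CochranQResult:
    Q: float
    df: int
    pvalue: float
    pooled: float


def cochran_q(estimates: Iterable[float], variances: Iterable[float]) -> CochranQResult:
    """Cochran's Q heterogeneity statistic with inverse-variance weights:
    Q = sum_i w_i (theta_i - theta_bar_w)^2, df = k - 1."""
    th = np.asarray(list(estimates), dtype=float)
    v = np.asarray(list(variances), dtype=float)
    if len(th) == 0 or (v <= 0).any():
        raise ValueError("need >=1 estimate with positive variances")
    w = 1.0 / v
    pooled = float(np.sum(w * th) / np.sum(w))
    Q = float(np.sum(w * (th - pooled)**2))
    df = len(th) - 1
    p = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    return CochranQResult(Q, df, p, pooled)


def _log_rr(a, na, b, nb):
    """log relative risk and its variance, Haldane-Anscombe corrected."""
    if 0 in (a, b, na - a, nb - b):
        a, b, na, nb = a + 0.5, b + 0.5, na + 1.0, nb + 1.0
    est = np.log((a / na) / (b / nb))
    var = 1 / a - 1 / na + 1 / b - 1 / nb
    return est, max(var, 1e-12)


def _stratum_counts(rates: pd.DataFrame, outcome: str, sex: str, band: str):
    row = rates[(rates["outcome"] == outcome) & (rates["sex"] == sex)
                & (rates["age_band"] == band)]
    if not len(row):
        return None
    return int(row["numerator"].iloc[0]), int(row["denominator"].iloc[0])


def country_comparison(rates_a: pd.DataFrame, rates_b: pd.DataFrame,
                       labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Compare outcome rates between two populations with aligned strata.

    Per outcome: a Mantel-Haenszel stratified chi-squared for the country
    effect controlling age band and sex; Cochran's Q across age strata of the
    country log-RR (pattern-over-age similarity); and Q (df = 1) contrasting
    the two countries' pooled female:male log-RRs (sex-effect difference).
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    bands = sorted(set(rates_a["age_band"]) - {"all"})
    out_rows = []
    for outcome in OUTCOMES:
        tables = []
        age_log_rr, age_var = [], []
        for band in bands:
            num_a = den_a = num_b = den_b = 0
            for sex in ("F", "M"):
                ca = _stratum_counts(rates_a, outcome, sex, band)
                cb = _stratum_counts(rates_b, outcome, sex, band)
                if ca is None or cb is None:
                    continue
                if ca[1] > 0 and cb[1] > 0:
                    tables.append(np.array([[ca[0], ca[1] - ca[0]],
                                            [cb[0], cb[1] - cb[0]]]) + 0.5)
                num_a, den_a = num_a + ca[0], den_a + ca[1]
                num_b, den_b = num_b + cb[0], den_b + cb[1]
            if den_a and den_b:
                est, var = _log_rr(num_a, den_a, num_b, den_b)
                age_log_rr.append(est)
                age_var.append(var)
        mh_stat = mh_p = np.nan
        if tables:
            st = StratifiedTable(tables)
            res = st.test_null_odds(correction=False)
            mh_stat, mh_p = float(res.statistic), float(res.pvalue)
        q_age = cochran_q(age_log_rr, age_var) if len(age_log_rr) > 1 else None

        # pooled sex effect (F vs M) per country, contrasted across countries
        sex_effects = []
        for rates in (rates_a, rates_b):
            f = _agg_counts(rates, outcome, "F")
            m = _agg_counts(rates, outcome, "M")
            if f and m:
                sex_effects.append(_log_rr(f[0], f[1], m[0], m[1]))
        q_sex = cochran_q([e for e, _ in sex_effects],
                          [v for _, v in sex_effects]) \
            if len(sex_effects) == 2 else None

        out_rows.append({
            "outcome": outcome,
            "mh_chi2": mh_stat, "mh_p": mh_p,
            "q_age": q_age.Q if q_age else np.nan,
            "q_age_df": q_age.df if q_age else 0,
            "q_age_p": q_age.pvalue if q_age else np.nan,
            "q_sex": q_sex.Q if q_sex else np.nan,
            "q_sex_p": q_sex.pvalue if q_sex else np.nan,
            "countries": f"{labels[0]} vs {labels[1]}",
        })
    return pd.DataFrame(out_rows)


def _agg_counts(rates: pd.DataFrame, outcome: str, sex: str):
    sub = rates[(rates["outcome"] == outcome) & (rates["sex"] == sex)
                & (rates["age_band"] != "all")]
    if not len(sub):
        return None
    return int(sub["numerator"].sum()), int(sub["denominator"].sum())


def treatment_contacts(cohort: Cohort, diagnoses: pd.DataFrame,
                       code_map: CodeMap) -> dict:
    """Specialist/primary treatment-contact summaries among MDD cases.

    Counts MDD-coded contacts per person and setting within follow-up; reports
    median and IQR per setting, the share with exactly one contact (among
    users of the setting), the share referred (any specialist contact after a
    first primary-care contact) and the share ever admitted as inpatient.
    """
    cases = cohort.cases
    if not len(cases):
        return {"n_cases": 0}
    d = diagnoses[diagnoses["person_id"].isin(cases.index)]
    mask = code_map.match_mask("mdd", d["icd_version"].to_numpy(),
                               d["code"].to_numpy())
    d = d[mask]
    exit_by_pid = cases["exit_date"]
    d = d[d["date"].to_numpy() < d["person_id"].map(exit_by_pid).to_numpy()]

    result: dict = {"n_cases": int(len(cases))}
    counts_by_setting = {}
    for setting in ("primary", "specialist_outpatient", "specialist_inpatient"):
        counts = d[d["setting"] == setting].groupby("person_id").size()
        counts = counts.reindex(cases.index, fill_value=0)
        counts_by_setting[setting] = counts
        users = counts[counts > 0]
        q1, med, q3 = np.percentile(users, [25, 50, 75]) if len(users) \
            else (np.nan,) * 3
        result[setting] = {
            "median": float(med), "iqr": float(q3 - q1) if len(users) else np.nan,
            "n_users": int(len(users)),
            "pct_single_contact": float((users == 1).mean() * 100) if len(users) else np.nan,
        }
    spec = d[d["setting"].isin(["specialist_outpatient", "specialist_inpatient"])]
    prim = d[d["setting"] == "primary"]
    first_primary = prim.groupby("person_id")["date"].min()
    last_spec = spec.groupby("person_id")["date"].max()
    joint = pd.concat([first_primary.rename("p"), last_spec.rename("s")], axis=1)
    referred = joint["p"].notna() & (joint["s"] > joint["p"])
    n_primary_users = int(first_primary.size)
    result["pct_referred"] = float(referred.sum() / n_primary_users * 100) \
        if n_primary_users else np.nan
    result["pct_ever_inpatient"] = float(
        (counts_by_setting["specialist_inpatient"] > 0).mean() * 100)
    return result
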