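"""Register readers, first-diagnosis resolution and cohort selection.

Implements the study-population rules used throughout: a birth-year window,
restriction to persons born in-country, exclusion of cases first diagnosed
before a minimum age, and exclusion of cases with insufficient follow-up after
first diagnosis (with suicide deaths optionally retained because suicide is an
outcome of interest).  Every exclusion is counted in a ledger keyed by rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .codes import CodeMap
from .config import CohortSpec
from .simulate import (DIAGNOSES_COLUMNS, FILLS_COLUMNS, PERSONS_COLUMNS,
                       RegistryBundle, TRUTH_COLUMNS)

__all__ = ["read_registry", "first_diagnosis", "first_diagnosis_table",
           "select_cohort", "Cohort"]

VALID_SETTINGS = {"specialist_outpatient", "specialist_inpatient", "primary"}

# fixed rule order; the ledger is reported under these keys
RULE_ORDER = ["birth_year", "born_in_country", "min_diagnosis_age",
              "min_followup", "unobservable"]


def _reject(report: list, file: str, row: int, reason: str, severity: str = "error"):
    report.append({"file": file, "row": row, "severity": severity, "reason": reason})


def read_registry(directory) -> RegistryBundle:
    """Read a register directory written by :func:`liabreg.simulate.write_registry`.

    Malformed rows are dropped and recorded (with 1-based data-row numbers) in
    ``bundle.report``.  A child referencing an unknown parent keeps its row but
    the parent link is cleared (treated as founder) with a warning.  Duplicate
    person ids raise ``ValueError``; missing files raise ``FileNotFoundError``.
    """
    directory = Path(directory)
    report: list[dict] = []
    for name in ("persons.csv", "diagnoses.csv", "prescriptions.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"required register file missing: {name}")

    # ----- persons ---------------------------------------------------------
    raw = pd.read_csv(directory / "persons.csv", dtype=str, keep_default_na=False)
    n = len(raw)
    pid = pd.to_numeric(raw.get("person_id", pd.Series([""] * n)), errors="coerce")
    by = pd.to_numeric(raw.get("birth_year"), errors="coerce")
    death = pd.to_numeric(raw.get("death_year"), errors="coerce")
    emig = pd.to_numeric(raw.get("emigration_year"), errors="coerce")
    ok = pd.Series(True, index=raw.index)
    for i in raw.index[pid.isna()]:
        _reject(report, "persons.csv", i + 1, "missing or non-numeric person_id")
        ok[i] = False
    for i in raw.index[ok & ~raw["sex"].isin(["F", "M"])]:
        _reject(report, "persons.csv", i + 1, f"invalid sex {raw.at[i, 'sex']!r}")
        ok[i] = False
    for i in raw.index[ok & by.isna()]:
        _reject(report, "persons.csv", i + 1, "missing birth_year")
        ok[i] = False
    bad_death = ok & death.notna() & (death < by + 0.5)
    for i in raw.index[bad_death]:
        _reject(report, "persons.csv", i + 1, "death before birth")
        ok[i] = False
    if pid[ok].duplicated().any():
        dupes = pid[ok][pid[ok].duplicated()].astype(int).tolist()
        raise ValueError(f"duplicate person_id(s): {dupes[:5]}")

    persons = pd.DataFrame({
        "person_id": pid[ok].astype(np.int64),
        "sex": raw.loc[ok, "sex"],
        "birth_year": by[ok].astype(np.int64),
        "mother_id": pd.array(pd.to_numeric(raw.loc[ok, "mother_id"], errors="coerce"), dtype="Int64"),
        "father_id": pd.array(pd.to_numeric(raw.loc[ok, "father_id"], errors="coerce"), dtype="Int64"),
        "death_year": death[ok],
        "emigration_year": emig[ok],
        "born_in_country": raw.loc[ok, "born_in_country"].isin(["True", "true", "1"]),
        "death_cause": raw.loc[ok, "death_cause"],
    }).reset_index(drop=True)

    known = set(persons["person_id"])
    for col in ("mother_id", "father_id"):
        vals = persons[col]
        unknown = vals.notna() & ~vals.isin(known)
        for i in persons.index[unknown]:
            _reject(report, "persons.csv", int(i) + 1,
                    f"unknown {col} {int(vals[i])}; treated as founder", "warning")
        persons.loc[unknown, col] = pd.NA

    birth_date = persons.set_index("person_id")["birth_year"] + 0.5

    # ----- diagnoses -------------------------------------------------------
    raw = pd.read_csv(directory / "diagnoses.csv", dtype=str, keep_default_na=False)
    pid = pd.to_numeric(raw.get("person_id"), errors="coerce")
    date = pd.to_numeric(raw.get("date"), errors="coerce")
    ver = pd.to_numeric(raw.get("icd_version"), errors="coerce")
    ok = pd.Series(True, index=raw.index)
    checks = [
        (pid.isna() | ~pid.isin(known), "unknown or invalid person_id"),
        (date.isna(), "invalid date"),
        (~ver.isin([8, 9, 10]), "icd_version not in {8,9,10}"),
        (raw["code"].str.len() == 0, "empty code"),
        (~raw["setting"].isin(VALID_SETTINGS), "invalid care setting"),
    ]
    for mask, reason in checks:
        for i in raw.index[ok & mask]:
            _reject(report, "diagnoses.csv", i + 1, reason)
        ok &= ~mask
    before_birth = ok & (date < pid.map(birth_date))
    for i in raw.index[before_birth]:
        _reject(report, "diagnoses.csv", i + 1, "event before birth")
    ok &= ~before_birth
    diagnoses = pd.DataFrame({
        "person_id": pid[ok].astype(np.int64), "date": date[ok],
        "icd_version": ver[ok].astype(int), "code": raw.loc[ok, "code"],
        "setting": raw.loc[ok, "setting"],
    }).reset_index(drop=True)

    # ----- prescriptions ---------------------------------------------------
    raw = pd.read_csv(directory / "prescriptions.csv", dtype=str, keep_default_na=False)
    pid = pd.to_numeric(raw.get("person_id"), errors="coerce")
    date = pd.to_numeric(raw.get("date"), errors="coerce")
    days = pd.to_numeric(raw.get("days_supplied"), errors="coerce")
    ok = pd.Series(True, index=raw.index)
    checks = [
        (pid.isna() | ~pid.isin(known), "unknown or invalid person_id"),
        (date.isna(), "invalid date"),
        (days.isna() | (days <= 0), "days_supplied must be positive"),
    ]
    for mask, reason in checks:
        for i in raw.index[ok & mask]:
            _reject(report, "prescriptions.csv", i + 1, reason)
        ok &= ~mask
    fills = pd.DataFrame({
        "person_id": pid[ok].astype(np.int64), "date": date[ok],
        "drug_class": raw.loc[ok, "drug_class"],
        "days_supplied": days[ok].astype(int),
    }).reset_index(drop=True)

    truth = None
    if (directory / "truth.csv").exists():
        truth = pd.read_csv(directory / "truth.csv")
        truth = truth.reindex(columns=TRUTH_COLUMNS)

    return RegistryBundle(
        persons=persons.reindex(columns=PERSONS_COLUMNS),
        diagnoses=diagnoses.reindex(columns=DIAGNOSES_COLUMNS),
        fills=fills.reindex(columns=FILLS_COLUMNS),
        truth=truth,
        report=pd.DataFrame(report, columns=["file", "row", "severity", "reason"]),
    )


def first_diagnosis_table(diagnoses: pd.DataFrame, disorder: str, code_map: CodeMap,
                          settings=None) -> pd.Series:
    """Earliest matching diagnosis date per person (person_id-indexed Series)."""
    if not len(diagnoses):
        return pd.Series(dtype=float, name="date")
    mask = code_map.match_mask(disorder, diagnoses["icd_version"].to_numpy(),
                               diagnoses["code"].to_numpy())
    if settings is not None:
        mask &= diagnoses["setting"].isin(set(settings)).to_numpy()
    sub = diagnoses.loc[mask, ["person_id", "date"]]
    return sub.groupby("person_id")["date"].min()


def first_diagnosis(events: pd.DataFrame, person_id: int, disorder: str,
                    code_map: CodeMap, settings=None) -> Optional[float]:
    """Date of the person's earliest event matching ``disorder``, or None."""
    table = first_diagnosis_table(events[events["person_id"] == person_id],
                                  disorder, code_map, settings)
    return float(table.iloc[0]) if len(table) else None


@dataclass
class Cohort:
    """A selected study population.

    ``members`` is indexed by person_id with per-member follow-up windows
    (ages, half-open ``[entry_age, exit_age)``), case flags and first-MDD
    timing.  ``ledger`` counts exclusions per rule in the fixed order applied.
    """

    members: pd.DataFrame
    spec: CohortSpec
    ledger: dict[str, int] = field(default_factory=dict)
    register_window: tuple[float, float] = (1975.0, 2013.0)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def cases(self) -> pd.DataFrame:
        return self.members[self.members["is_case"]]


def select_cohort(bundle: RegistryBundle, spec: CohortSpec, code_map: CodeMap,
                  register_window: Optional[tuple[float, float]] = None,
                  disorder: str = "mdd") -> Cohort:
    """Apply the cohort-selection rules and return the cohort plus ledger.

    Rules are applied in the fixed order: birth-year window; born-in-country;
    first diagnosis before ``min_diagnosis_age`` (cases removed entirely);
    insufficient follow-up after first diagnosis (cases only, suicide deaths
    kept when ``keep_suicide_deaths``); unobservable follow-up window.
    """
    spec.validate()
    if register_window is None:
        register_window = bundle.meta.get("register_window")
    if register_window is None:
        # fall back to the observed event span (documented approximation)
        dates = pd.concat([bundle.diagnoses["date"], bundle.fills["date"]])
        register_window = (float(np.floor(dates.min())) if len(dates) else 1975.0,
                           float(np.ceil(dates.max())) if len(dates) else 2013.0)
    reg_start, reg_end = float(register_window[0]), float(register_window[1])

    persons = bundle.persons.set_index("person_id")
    first_mdd = first_diagnosis_table(bundle.diagnoses, disorder, code_map,
                                      settings=spec.care_settings)

    df = persons.copy()
    df["birth_date"] = df["birth_year"] + 0.5
    df["first_mdd_date"] = df.index.map(first_mdd)
    df["first_mdd_age"] = df["first_mdd_date"] - df["birth_date"]
    exit_date = np.fmin.reduce([
        df["death_year"].fillna(np.inf).to_numpy(dtype=float),
        df["emigration_year"].fillna(np.inf).to_numpy(dtype=float),
        np.full(len(df), reg_end),
        (df["birth_date"] + spec.age_cap).to_numpy(dtype=float),
    ])
    df["exit_date"] = exit_date
    df["entry_date"] = np.maximum(df["birth_date"] + spec.min_diagnosis_age, reg_start)
    df["entry_age"] = df["entry_date"] - df["birth_date"]
    df["exit_age"] = df["exit_date"] - df["birth_date"]
    df["is_case"] = df["first_mdd_date"].notna() & (df["first_mdd_date"] < df["exit_date"])
    df["suicide_death"] = (df["death_cause"] == "suicide") & df["death_year"].notna()

    ledger: dict[str, int] = {}
    y0, y1 = spec.birth_year_range

    keep = df["birth_year"].between(y0, y1)
    ledger["birth_year"] = int((~keep).sum())
    df = df[keep]

    if spec.require_born_in_country:
        keep = df["born_in_country"].astype(bool)
        ledger["born_in_country"] = int((~keep).sum())
        df = df[keep]
    else:
        ledger["born_in_country"] = 0

    early = df["first_mdd_age"].notna() & (df["first_mdd_age"] < spec.min_diagnosis_age)
    ledger["min_diagnosis_age"] = int(early.sum())
    df = df[~early]

    short = df["is_case"] & \
        ((df["exit_date"] - df["first_mdd_date"]) < spec.min_followup_after_first_dx)
    if spec.keep_suicide_deaths:
        short &= ~df["suicide_death"]
    ledger["min_followup"] = int(short.sum())
    df = df[~short]

    unobservable = df["exit_age"] <= df["entry_age"]
    ledger["unobservable"] = int(unobservable.sum())
    df = df[~unobservable]

    if not len(df):
        import warnings
        warnings.warn("cohort selection excluded everyone", stacklevel=2)

    members = df[["sex", "birth_year", "born_in_country", "entry_age", "exit_age",
                  "entry_date", "exit_date", "first_mdd_date", "first_mdd_age",
                  "is_case", "death_year", "death_cause", "suicide_death",
                  "mother_id", "father_id"]].copy()
    return Cohort(members=members, spec=spec, ledger=ledger,
                  register_window=(reg_start, reg_end))
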