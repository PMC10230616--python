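"""Synthetic national-register generator with an ACE liability structure.

The generator builds two-generation pedigrees (founder parents, child
sibships), assigns each person a latent liability

    L = A + C + E,   Var(L) = 1,

where A is additive genetic (child A is the mid-parent mean plus segregation
noise of variance a2/2), C is drawn once per mother-sibship (so full and
maternal half-siblings share it fully) and E is unique.  Lifetime MDD case
status is a liability-threshold rule with sex-specific thresholds calibrated
to the configured lifetime risk and female:male risk ratio.  Cases receive an
age at onset, register diagnosis contacts, optional recurrence / diagnostic
cross-over / self-harm / suicide events, comorbid-disorder diagnoses driven by
correlated liabilities, and antidepressant prescription fills.  Censoring by
death, emigration and the register window is applied throughout.

All dates are decimal years; births are placed at mid-year.  Intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import OnsetModel, SimConfig

__all__ = ["RegistryBundle", "simulate_registry", "write_registry", "simulate_sib_pairs_config"]

PERSONS_COLUMNS = ["person_id", "sex", "birth_year", "mother_id", "father_id",
                   "death_year", "emigration_year", "born_in_country", "death_cause"]
DIAGNOSES_COLUMNS = ["person_id", "date", "icd_version", "code", "setting"]
FILLS_COLUMNS = ["person_id", "date", "drug_class", "days_supplied"]
TRUTH_COLUMNS = ["person_id", "A", "C", "E", "liability", "is_case", "onset_age"]

_COMORBID_CODE = {
    "anxiety": "F41.9", "adhd": "F90.0", "asd": "F84.0", "bipolar": "F31.9",
    "eating": "F50.0", "schizophrenia": "F20.9", "substance_use": "F10.2",
}
_SELF_HARM_CODES = np.array(["X60", "X61", "X78", "X84"])
_ECT_CODE = "DA024"


@dataclass
class RegistryBundle:
    """In-memory register: persons, diagnosis events, prescription fills, and
    (when simulated) a truth sidecar with the latent liabilities."""

    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    fills: pd.DataFrame
    truth: Optional[pd.DataFrame] = None
    report: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for frame, cols in ((self.persons, PERSONS_COLUMNS),
                            (self.diagnoses, DIAGNOSES_COLUMNS),
                            (self.fills, FILLS_COLUMNS)):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"bundle frame missing columns {sorted(missing)}")


def _onset_ages(model: OnsetModel, u: np.ndarray) -> np.ndarray:
    """Quantile transform of uniforms through the configured onset family."""
    lo, hi = model.support
    if model.family == "uniform":
        return lo + u * (hi - lo)
    a = (lo - model.mean) / model.sd
    b = (hi - model.mean) / model.sd
    return stats.truncnorm.ppf(u, a, b, loc=model.mean, scale=model.sd)


def _segment_starts(sizes: np.ndarray) -> np.ndarray:
    return np.concatenate(([0], np.cumsum(sizes)[:-1]))


def simulate_registry(config: SimConfig) -> RegistryBundle:
    """Generate a full synthetic register bundle from ``config``.

    Deterministic given ``config`` (including its seed).  Raises ``ValueError``
    on invalid configurations (zero families, a2+c2>1, degenerate onset).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a2, c2, e2 = config.a2, config.c2, config.e2
    by_lo, by_hi = config.birth_year_range
    reg_start, reg_end = (float(config.register_window[0]),
                          float(config.register_window[1]))

    # ----- pedigree structure ---------------------------------------------
    F = config.n_families
    if config.sibship_size is not None:
        sizes = np.full(F, config.sibship_size, dtype=int)
    else:
        sizes = np.maximum(rng.poisson(config.mean_children_per_mother, F), 1)
    half_fam = (rng.random(F) < config.half_sib_family_fraction) & (sizes >= 2)

    n_children = int(sizes.sum())
    fam = np.repeat(np.arange(F), sizes)                       # family of each child
    starts = _segment_starts(sizes)
    child_rank = np.arange(n_children) - starts[fam]           # 0..s-1 within sibship

    # split points for half-sib families: first k children get father 1
    split = np.ones(F, dtype=int)
    split[half_fam] = rng.integers(1, sizes[half_fam])
    # father slot 0 or 1 for each child (slot 1 only in half-sib families)
    father_slot = np.where(half_fam[fam] & (child_rank >= split[fam]), 1, 0)

    # ----- founder liabilities --------------------------------------------
    A_m = rng.normal(0.0, np.sqrt(a2), F) if a2 > 0 else np.zeros(F)
    A_f = rng.normal(0.0, np.sqrt(a2), (F, 2)) if a2 > 0 else np.zeros((F, 2))
    C_fam = rng.normal(0.0, np.sqrt(c2), F) if c2 > 0 else np.zeros(F)

    # ----- child liabilities ----------------------------------------------
    A_child = 0.5 * (A_m[fam] + A_f[fam, father_slot])
    if a2 > 0:
        A_child = A_child + rng.normal(0.0, np.sqrt(a2 / 2.0), n_children)
    C_child = C_fam[fam]
    E_child = rng.normal(0.0, np.sqrt(e2), n_children) if e2 > 0 else np.zeros(n_children)
    liability = A_child + C_child + E_child
    if config.half_sib_env_shift:
        liability = liability + config.half_sib_env_shift * half_fam[fam]

    # ----- demography ------------------------------------------------------
    child_sex_female = rng.random(n_children) < 0.5
    child_birth = rng.integers(by_lo, by_hi + 1, n_children)

    mother_by = np.full(F, 10**9)
    np.minimum.at(mother_by, fam, child_birth)
    mother_birth = mother_by - rng.integers(20, 36, F)
    father_birth = mother_by[:, None] - rng.integers(20, 36, (F, 2))

    # ----- person ids (mothers, used fathers, children; ascending) ---------
    mother_id = np.arange(1, F + 1)
    father_id = F + 1 + 2 * np.arange(F)            # slots F+1+2i, F+2+2i
    child_id = 3 * F + 1 + np.arange(n_children)
    father_used = np.zeros((F, 2), dtype=bool)
    father_used[np.arange(F), 0] = True
    father_used[half_fam, 1] = True
    fu = father_used.ravel()
    n_f = int(fu.sum())
    all_father_ids = np.column_stack([father_id, father_id + 1]).ravel()

    # ----- founders are register persons too -------------------------------
    # their C/E are personal draws (their own sibships are unmodelled)
    n_par = F + n_f
    par_A = np.concatenate([A_m, A_f.ravel()[fu]])
    par_C = rng.normal(0.0, np.sqrt(c2), n_par) if c2 > 0 else np.zeros(n_par)
    par_E = rng.normal(0.0, np.sqrt(e2), n_par) if e2 > 0 else np.zeros(n_par)

    n_all = n_par + n_children
    pid = np.concatenate([mother_id, all_father_ids[fu], child_id]).astype(np.int64)
    sex_female = np.concatenate([np.ones(F, bool), np.zeros(n_f, bool),
                                 child_sex_female])
    birth_year = np.concatenate([mother_birth, father_birth.ravel()[fu],
                                 child_birth])
    birth_date = birth_year + 0.5
    A_all = np.concatenate([par_A, A_child])
    C_all = np.concatenate([par_C, C_child])
    E_all = np.concatenate([par_E, E_child])
    liability = np.concatenate([par_A + par_C + par_E, liability])
    mother_of = np.concatenate([np.full(n_par, -1), mother_id[fam]])
    father_of = np.concatenate([np.full(n_par, -1),
                                father_id[fam] + father_slot])
    born_in = np.concatenate([np.ones(n_par, bool),
                              rng.random(n_children) > 0.02])

    # ----- case status -----------------------------------------------------
    K_f, K_m = config.sex_specific_risks()
    t_f, t_m = stats.norm.isf(K_f), stats.norm.isf(K_m)
    threshold = np.where(sex_female, t_f, t_m)
    is_case = liability > threshold

    onset_age = np.full(n_all, np.nan)
    n_cases = int(is_case.sum())
    if n_cases:
        if config.liability_graded_onset:
            # higher liability -> smaller tail quantile -> earlier onset
            K_sex = np.where(sex_female, K_f, K_m)[is_case]
            u = np.clip(stats.norm.sf(liability[is_case]) / K_sex, 1e-9, 1 - 1e-9)
        else:
            u = rng.random(n_cases)
        onset_age[is_case] = _onset_ages(config.onset, u)

    # ----- censoring -------------------------------------------------------
    death_age = np.full(n_all, np.inf)
    emig_age = np.full(n_all, np.inf)
    if config.annual_mortality_hazard > 0:
        death_age = rng.exponential(1.0 / config.annual_mortality_hazard, n_all)
    if config.annual_emigration_hazard > 0:
        emig_age = rng.exponential(1.0 / config.annual_emigration_hazard, n_all)
    death_cause = np.where(death_age < np.inf, "other", "")

    # suicide among cases, after onset; overrides later natural death
    if n_cases and config.suicide_prob > 0:
        sui = is_case & (rng.random(n_all) < config.suicide_prob)
        lag = rng.exponential(config.event_lag_means.get("suicide", 5.0), n_all)
        sui_age = onset_age + lag
        take = sui & (sui_age < death_age) & (sui_age < emig_age)
        death_age = np.where(take, sui_age, death_age)
        death_cause = np.where(take, "suicide", death_cause)

    # keep only the earlier of death/emigration, and only if observed in-window
    emig_age = np.where(emig_age < death_age, emig_age, np.inf)
    death_age = np.where(death_age <= emig_age, death_age, np.inf)
    death_year = birth_date + death_age
    emig_year = birth_date + emig_age
    death_year = np.where(death_year < reg_end, death_year, np.nan)
    emig_year = np.where(emig_year < reg_end, emig_year, np.nan)
    death_cause = np.where(np.isfinite(death_year), death_cause, "")

    exit_date = np.fmin(np.fmin(np.nan_to_num(death_year, nan=np.inf),
                                np.nan_to_num(emig_year, nan=np.inf)), reg_end)

    persons = pd.DataFrame({
        "person_id": pid,
        "sex": np.where(sex_female, "F", "M"),
        "birth_year": birth_year,
        "mother_id": pd.array(np.where(mother_of < 0, None, mother_of),
                              dtype="Int64"),
        "father_id": pd.array(np.where(father_of < 0, None, father_of),
                              dtype="Int64"),
        "death_year": death_year,
        "emigration_year": emig_year,
        "born_in_country": born_in,
        "death_cause": death_cause,
    })

    # ----- diagnosis events -------------------------------------------------
    diag_pid: list[np.ndarray] = []
    diag_date: list[np.ndarray] = []
    diag_ver: list[np.ndarray] = []
    diag_code: list[np.ndarray] = []
    diag_setting: list[np.ndarray] = []

    def _emit(pids, dates, versions, codes, settings):
        dates = np.asarray(dates, dtype=float)
        keep = (dates >= np.maximum(reg_start, birth_date[np.searchsorted(pid, pids)])) \
            & (dates < exit_date[np.searchsorted(pid, pids)])
        diag_pid.append(np.asarray(pids)[keep])
        diag_date.append(dates[keep])
        diag_ver.append(np.asarray(versions, dtype=int)[keep])
        diag_code.append(np.asarray(codes, dtype=object)[keep])
        diag_setting.append(np.asarray(settings, dtype=object)[keep])
        return keep

    def _mdd_code_for_year(years: np.ndarray, recurrent: bool, r: np.ndarray):
        """Era-appropriate MDD code; r is a uniform draw for subcode choice."""
        versions = np.where(years < 1987, 8, np.where(years < 1997, 9, 10))
        codes = np.empty(len(years), dtype=object)
        icd10 = versions == 10
        if recurrent:
            codes[icd10] = np.where(r[icd10] < 0.5, "F33.1", "F33.0")
            codes[versions == 9] = "296.3"
            codes[versions == 8] = "296.0"
        else:
            sub = np.select([r < 0.45, r < 0.65, r < 0.80], ["F32.1", "F32.0", "F32.2"],
                            default="F32.9")
            codes[icd10] = sub[icd10]
            codes[versions == 9] = np.where(r[versions == 9] < 0.6, "311", "296.2")
            codes[versions == 8] = np.where(r[versions == 8] < 0.6, "300.4", "296.0")
        return versions, codes

    case_idx = np.flatnonzero(is_case)
    onset_date = birth_date + onset_age
    settings_pool = np.array(["specialist_outpatient", "specialist_inpatient", "primary"])

    diagnosed = np.zeros(n_all, dtype=bool)
    if n_cases:
        dates = onset_date[case_idx]
        r = rng.random(n_cases)
        ver, codes = _mdd_code_for_year(dates.astype(int), False, r)
        setting = settings_pool[rng.choice(3, n_cases, p=[0.70, 0.10, 0.20])]
        kept = _emit(pid[case_idx], dates, ver, codes, setting)
        diagnosed[case_idx[kept]] = True

    dx_idx = np.flatnonzero(diagnosed)
    n_dx = len(dx_idx)

    # follow-up contacts: geometric number of extra MDD-coded contacts
    if n_dx:
        n_extra = rng.geometric(0.27, n_dx) - 1
        rep = np.repeat(dx_idx, n_extra)
        if len(rep):
            gaps = rng.exponential(0.5, len(rep))
            cum = np.cumsum(gaps)
            # segmented cumsum: subtract the cumulative total before each segment
            seg_sizes = n_extra[n_extra > 0]
            seg_base = np.concatenate(([0.0], cum))[
                np.repeat(_segment_starts(seg_sizes), seg_sizes)]
            contact_dates = onset_date[rep] + (cum - seg_base)
            r = rng.random(len(rep))
            ver, codes = _mdd_code_for_year(contact_dates.astype(int), False, r)
            setting = settings_pool[rng.choice(3, len(rep), p=[0.65, 0.10, 0.25])]
            _emit(pid[rep], contact_dates, ver, codes, setting)

    def _case_event(prob: float, lag_mean: float):
        """(indices, event dates) for a per-diagnosed-case lagged event."""
        if n_dx == 0 or prob <= 0:
            return np.array([], dtype=int), np.array([])
        hit = rng.random(n_dx) < prob
        idx = dx_idx[hit]
        dates = onset_date[idx] + rng.exponential(lag_mean, len(idx))
        return idx, dates

    # recurrence -> recurrent-MDD codes
    idx, dates = _case_event(config.recurrence_prob,
                             config.event_lag_means.get("recurrence", 3.0))
    if len(idx):
        r = rng.random(len(idx))
        ver, codes = _mdd_code_for_year(dates.astype(int), True, r)
        setting = settings_pool[rng.choice(3, len(idx), p=[0.70, 0.15, 0.15])]
        _emit(pid[idx], dates, ver, codes, setting)

    # diagnostic cross-over -> bipolar or schizophrenia-spectrum codes
    idx, dates = _case_event(config.crossover_prob,
                             config.event_lag_means.get("crossover", 4.0))
    if len(idx):
        codes = np.where(rng.random(len(idx)) < 0.6, "F31.9", "F20.9")
        _emit(pid[idx], dates, np.full(len(idx), 10), codes,
              settings_pool[rng.choice(3, len(idx), p=[0.55, 0.35, 0.10])])

    # self-harm -> external-cause codes
    idx, dates = _case_event(config.selfharm_prob,
                             config.event_lag_means.get("selfharm", 2.0))
    if len(idx):
        codes = _SELF_HARM_CODES[rng.integers(0, len(_SELF_HARM_CODES), len(idx))]
        _emit(pid[idx], dates, np.full(len(idx), 10), codes,
              np.full(len(idx), "specialist_inpatient", dtype=object))

    # ----- comorbid disorders ----------------------------------------------
    for name, com in config.comorbidities.items():
        rho = com.liability_corr
        L_d = rho * liability + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, 1, n_all)
        affected = L_d > stats.norm.isf(com.lifetime_risk)
        idx = np.flatnonzero(affected)
        if not len(idx):
            continue
        ages = _onset_ages(com.onset, rng.random(len(idx)))
        dates = birth_date[idx] + ages
        code = _COMORBID_CODE.get(name, "F99")
        _emit(pid[idx], dates, np.full(len(idx), 10),
              np.full(len(idx), code, dtype=object),
              settings_pool[rng.choice(3, len(idx), p=[0.70, 0.10, 0.20])])

    # ----- treatment: prescription fills and ECT ---------------------------
    fill_rows: list[tuple] = []
    tp = config.treatment
    if tp is not None and n_dx:
        classes = np.array(sorted(tp.class_probs))
        class_p = np.array([tp.class_probs[c] for c in classes])
        treated = dx_idx[rng.random(n_dx) < tp.treated_fraction]
        for i in treated:
            person = int(pid[i])
            end = exit_date[i]
            n_ep = 1 + rng.poisson(max(tp.mean_episodes - 1.0, 0.0))
            t = onset_date[i] + rng.uniform(0, 60) / 365.25
            combo = rng.random() < tp.combination_fraction
            augment = rng.random() < tp.augmentation_fraction
            drug = str(rng.choice(classes, p=class_p))
            for ep in range(n_ep):
                # most patients continue their previous medication
                if ep > 0 and rng.random() < 0.35:
                    drug = str(rng.choice(classes, p=class_p))
                n_fill = 1 + rng.poisson(max(tp.mean_fills_per_episode - 1.0, 0.0))
                for _ in range(n_fill):
                    if t >= end or t >= reg_end:
                        break
                    fill_rows.append((person, t, drug, tp.days_supplied))
                    if combo and ep == 0:
                        other = str(rng.choice(classes))
                        if other == drug:
                            other = str(classes[(np.flatnonzero(classes == drug)[0] + 1)
                                                % len(classes)])
                        # concurrent partner fill: same date and supply
                        fill_rows.append((person, t, other, tp.days_supplied))
                    t += (tp.days_supplied + rng.uniform(0, tp.within_gap_max)) / 365.25
                if augment and ep == 0 and t < end:
                    fill_rows.append((person, t - tp.days_supplied / 365.25 / 2,
                                      "augmentation_agent", 14))
                t += rng.uniform(tp.between_gap_min, tp.between_gap_max) / 365.25
        # ECT procedures
        ect = dx_idx[rng.random(n_dx) < tp.ect_fraction]
        if len(ect):
            dates = onset_date[ect] + rng.exponential(1.0, len(ect))
            _emit(pid[ect], dates, np.full(len(ect), 10),
                  np.full(len(ect), _ECT_CODE, dtype=object),
                  np.full(len(ect), "specialist_inpatient", dtype=object))

    # ----- assemble frames --------------------------------------------------
    if diag_pid:
        diagnoses = pd.DataFrame({
            "person_id": np.concatenate(diag_pid).astype(int),
            "date": np.concatenate(diag_date),
            "icd_version": np.concatenate(diag_ver).astype(int),
            "code": np.concatenate(diag_code).astype(str),
            "setting": np.concatenate(diag_setting).astype(str),
        }).sort_values(["person_id", "date"], kind="mergesort").reset_index(drop=True)
    else:
        diagnoses = pd.DataFrame(columns=DIAGNOSES_COLUMNS)

    fills = pd.DataFrame(fill_rows, columns=FILLS_COLUMNS)
    if len(fills):
        pos = np.searchsorted(pid, fills["person_id"].to_numpy())
        in_window = (fills["date"].to_numpy() >= reg_start) \
            & (fills["date"].to_numpy() < exit_date[pos])
        fills = fills[in_window]
        fills = fills.sort_values(["person_id", "date"], kind="mergesort").reset_index(drop=True)

    truth = pd.DataFrame({
        "person_id": pid, "A": A_all, "C": C_all, "E": E_all,
        "liability": liability, "is_case": is_case, "onset_age": onset_age,
    })

    return RegistryBundle(persons=persons, diagnoses=diagnoses, fills=fills,
                          truth=truth,
                          meta={"config_hash": config.config_hash(),
                                "seed": config.seed,
                                "register_window": (reg_start, reg_end),
                                "n_families": F, "n_children": n_children})


def simulate_sib_pairs_config(n_full_pairs: int, n_half_pairs: int,
                              base: Optional[SimConfig] = None, **overrides) -> SimConfig:
    """Config whose fixed size-2 sibships yield exactly the requested numbers of
    full and maternal-half sibling pairs (one pair per family)."""
    import dataclasses as _dc

    n_fam = n_full_pairs + n_half_pairs
    cfg = base or SimConfig()
    cfg = _dc.replace(cfg, n_families=n_fam, sibship_size=2,
                      half_sib_family_fraction=n_half_pairs / n_fam if n_fam else 0.0,
                      **overrides)
    return cfg


def write_registry(bundle: RegistryBundle, directory) -> dict[str, Path]:
    """Write persons.csv, diagnoses.csv, prescriptions.csv (and truth.csv when
    present) under ``directory``.  Output is byte-stable for a given bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(df: pd.DataFrame, name: str, cols: list[str]) -> None:
        path = directory / name
        out = df.reindex(columns=cols)
        out.to_csv(path, index=False, float_format="%.6f")
        paths[name] = path

    _write(bundle.persons, "persons.csv", PERSONS_COLUMNS)
    _write(bundle.diagnoses, "diagnoses.csv", DIAGNOSES_COLUMNS)
    _write(bundle.fills, "prescriptions.csv", FILLS_COLUMNS)
    if bundle.truth is not None:
        _write(bundle.truth, "truth.csv", TRUTH_COLUMNS)
    return paths
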