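"""Shared fixtures: hand-built register bundles and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import liabreg as lr


def make_bundle(persons_rows, diagnosis_rows=(), fill_rows=(),
                register_window=(1975.0, 2013.0)) -> lr.RegistryBundle:
    """Build a typed RegistryBundle from plain tuples.

    persons_rows: (person_id, sex, birth_year, mother_id, father_id,
                   death_year, emigration_year, born_in_country, death_cause)
    diagnosis_rows: (person_id, date, icd_version, code, setting)
    fill_rows: (person_id, date, drug_class, days_supplied)
    """
    persons = pd.DataFrame(persons_rows, columns=[
        "person_id", "sex", "birth_year", "mother_id", "father_id",
        "death_year", "emigration_year", "born_in_country", "death_cause"])
    persons["mother_id"] = pd.array(persons["mother_id"], dtype="Int64")
    persons["father_id"] = pd.array(persons["father_id"], dtype="Int64")
    persons["death_year"] = persons["death_year"].astype(float)
    persons["emigration_year"] = persons["emigration_year"].astype(float)
    diagnoses = pd.DataFrame(list(diagnosis_rows), columns=[
        "person_id", "date", "icd_version", "code", "setting"])
    fills = pd.DataFrame(list(fill_rows), columns=[
        "person_id", "date", "drug_class", "days_supplied"])
    return lr.RegistryBundle(persons=persons, diagnoses=diagnoses, fills=fills,
                             meta={"register_window": register_window})


@pytest.fixture(scope="session")
def code_map():
    return lr.default_code_map()


@pytest.fixture(scope="session")
def six_person_bundle():
    """Each cohort-selection rule removes exactly one person; two remain."""
    SO = "specialist_outpatient"
    persons = [
        (1, "F", 1960, None, None, np.nan, np.nan, True, ""),    # birth-year rule
        (2, "M", 1980, None, None, np.nan, np.nan, False, ""),   # born-abroad rule
        (3, "F", 1990, None, None, np.nan, np.nan, True, ""),    # diagnosed age < 10
        (4, "M", 1980, None, None, np.nan, np.nan, True, ""),    # < 5 y follow-up
        (5, "F", 1985, None, None, np.nan, np.nan, True, ""),    # kept (case)
        (6, "M", 1995, None, None, np.nan, np.nan, True, ""),    # kept (non-case)
    ]
    diagnoses = [
        (3, 1999.9, 10, "F32.1", SO),   # age 9.4 at first code
        (4, 2010.0, 10, "F32.1", SO),   # register ends 2013 -> 3 y follow-up
        (5, 2000.0, 10, "F32.0", SO),   # age 14.5, 13 y follow-up
    ]
    return make_bundle(persons, diagnoses)


@pytest.fixture(scope="session")
def washout_bundle():
    """Two MDD cases probing the cross-over wash-out rule (1.0 y default):
    a bipolar code 0.3 y after first MDD (diagnostic uncertainty, excluded
    from the denominator) and one 5 y after (counts as cross-over)."""
    SO = "specialist_outpatient"
    persons = [
        (1, "F", 1975, None, None, np.nan, np.nan, True, ""),
        (2, "M", 1975, None, None, np.nan, np.nan, True, ""),
        (3, "F", 1976, None, None, np.nan, np.nan, True, ""),
    ]
    diagnoses = [
        (1, 1995.5, 10, "F32.1", SO),   # first MDD at age 20
        (1, 1995.8, 10, "F31.9", SO),   # bipolar at 20.3: inside wash-out
        (2, 2000.5, 10, "F32.1", SO),   # first MDD at age 25
        (2, 2005.5, 10, "F31.9", SO),   # bipolar at 30: cross-over
        (3, 1996.5, 10, "F32.9", SO),   # case with no further events
    ]
    return make_bundle(persons, diagnoses)


@pytest.fixture(scope="session")
def sim_bundle():
    """A moderate synthetic register shared across read-only tests."""
    cfg = lr.broad_preset(n_families=4000, seed=421)
    return lr.simulate_registry(cfg)


@pytest.fixture(scope="session")
def sim_cohort(sim_bundle, code_map):
    return lr.select_cohort(sim_bundle, lr.CohortSpec(), code_map)
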