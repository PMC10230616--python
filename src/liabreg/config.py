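"""Configuration objects for the synthetic register generator and cohort selection.

The simulator implements a liability-threshold population: each person carries a
latent liability L = A + C + E with additive-genetic (A), sibship-shared
environment (C) and unique environment (E) components scaled so Var(L) = 1.
``SimConfig`` holds the variance proportions, lifetime risk, demography and the
clinical-event probabilities the generator uses; ``CohortSpec`` holds the
register cohort-selection rules.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = [
    "OnsetModel",
    "Comorbidity",
    "TreatmentParams",
    "SimConfig",
    "CohortSpec",
    "broad_preset",
    "narrow_preset",
]


@dataclass
class OnsetModel:
    """Age-at-onset distribution for lifetime cases.

    ``family`` is ``"truncnorm"`` (normal truncated to ``support``) or
    ``"uniform"`` over ``support``.  Ages are in years; support is half-open.
    """

    family: str = "truncnorm"
    mean: float = 27.0
    sd: float = 8.0
    support: tuple[float, float] = (10.0, 49.0)

    def validate(self) -> None:
        if self.family not in {"truncnorm", "uniform"}:
            raise ValueError(f"unknown onset family {self.family!r}")
        lo, hi = self.support
        if not lo < hi:
            raise ValueError("degenerate onset support")
        if self.family == "truncnorm" and self.sd <= 0:
            raise ValueError(f"degenerate onset distribution: sd={self.sd}")


@dataclass
class Comorbidity:
    """A comorbid disorder generated from a liability correlated with MDD liability."""

    lifetime_risk: float
    liability_corr: float
    onset: OnsetModel = field(default_factory=OnsetModel)

    def validate(self, name: str = "") -> None:
        if not 0.0 < self.lifetime_risk < 1.0:
            raise ValueError(f"comorbidity {name}: lifetime_risk must be in (0,1)")
        if not -1.0 <= self.liability_corr <= 1.0:
            raise ValueError(f"comorbidity {name}: liability_corr must be in [-1,1]")
        self.onset.validate()


@dataclass
class TreatmentParams:
    """Prescription-fill generator for treated cases.

    Episode counts are 1 + Poisson(mean_episodes - 1); fills within an episode
    are 1 + Poisson(mean_fills_per_episode - 1) with short refill gaps, while
    consecutive episodes are separated by long gaps.  All durations in days.
    """

    treated_fraction: float = 0.68
    mean_episodes: float = 5.0
    mean_fills_per_episode: float = 2.5
    days_supplied: int = 30
    within_gap_max: float = 20.0
    between_gap_min: float = 120.0
    between_gap_max: float = 420.0
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "SSRI": 0.55,
            "SNRI": 0.22,
            "TCA": 0.08,
            "other_antidepressant": 0.15,
        }
    )
    combination_fraction: float = 0.14
    augmentation_fraction: float = 0.05
    ect_fraction: float = 0.016

    def validate(self) -> None:
        for name in ("treated_fraction", "combination_fraction",
                     "augmentation_fraction", "ect_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.days_supplied <= 0:
            raise ValueError("days_supplied must be positive")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")


def _default_comorbidities() -> dict[str, Comorbidity]:
    # Lifetime specialist-care risks in plausible Scandinavian ranges; the
    # liability correlations set the strength of comorbidity with MDD.
    return {
        "anxiety": Comorbidity(0.10, 0.55),
        "adhd": Comorbidity(0.04, 0.30, OnsetModel("truncnorm", 14.0, 6.0, (10.0, 49.0))),
        "asd": Comorbidity(0.012, 0.20, OnsetModel("truncnorm", 13.0, 5.0, (10.0, 49.0))),
        "bipolar": Comorbidity(0.015, 0.45),
        "eating": Comorbidity(0.012, 0.35, OnsetModel("truncnorm", 18.0, 5.0, (10.0, 49.0))),
        "schizophrenia": Comorbidity(0.01, 0.30),
        "substance_use": Comorbidity(0.05, 0.35),
    }


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic national register.

    Variance proportions ``a2`` (additive genetic) and ``c2`` (sibship-shared
    environment) define the ACE liability structure; ``e2 = 1 - a2 - c2`` is
    implied.  ``lifetime_risk_by_49`` is the sex-averaged lifetime risk K by
    the age cap; ``female_male_rr`` fixes the female:male lifetime-risk ratio
    via sex-specific thresholds.
    """

    n_families: int = 1000
    mean_children_per_mother: float = 2.3
    sibship_size: Optional[int] = None  # fixed sibship size override
    half_sib_family_fraction: float = 0.15
    birth_year_range: tuple[int, int] = (1965, 2000)
    register_window: tuple[int, int] = (1975, 2013)
    a2: float = 0.45
    c2: float = 0.05
    lifetime_risk_by_49: float = 0.072
    female_male_rr: float = 1.7
    onset: OnsetModel = field(default_factory=OnsetModel)
    liability_graded_onset: bool = False
    annual_emigration_hazard: float = 0.003
    annual_mortality_hazard: float = 0.001
    recurrence_prob: float = 0.31
    # excess cross-over hazard beyond what the correlated bipolar/schizophrenia
    # liabilities already induce among cases; total cross-over ~5% of cases
    crossover_prob: float = 0.02
    selfharm_prob: float = 0.07
    suicide_prob: float = 0.004
    # mean lag (years) from first MDD onset to each clinical event
    event_lag_means: dict[str, float] = field(
        default_factory=lambda: {"recurrence": 3.0, "crossover": 4.0,
                                 "selfharm": 2.0, "suicide": 5.0}
    )
    comorbidities: dict[str, Comorbidity] = field(default_factory=_default_comorbidities)
    treatment: Optional[TreatmentParams] = field(default_factory=TreatmentParams)
    half_sib_env_shift: float = 0.0  # additive liability shift for half-sibships
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if self.mean_children_per_mother <= 0:
            raise ValueError("mean_children_per_mother must be positive")
        if self.sibship_size is not None and self.sibship_size < 1:
            raise ValueError("sibship_size must be >= 1")
        if self.a2 < 0 or self.c2 < 0:
            raise ValueError("a2 and c2 must be non-negative")
        if self.a2 + self.c2 > 1.0 + 1e-12:
            raise ValueError(f"a2 + c2 = {self.a2 + self.c2} exceeds 1")
        if not 0.0 < self.lifetime_risk_by_49 < 1.0:
            raise ValueError("lifetime_risk_by_49 must be in (0,1)")
        if self.female_male_rr <= 0:
            raise ValueError("female_male_rr must be positive")
        b0, b1 = self.birth_year_range
        r0, r1 = self.register_window
        if b0 > b1 or r0 > r1:
            raise ValueError("year ranges must be ordered")
        if r1 < b0:
            raise ValueError("register_window must be within or after birth range start")
        for name in ("half_sib_family_fraction", "annual_emigration_hazard",
                     "annual_mortality_hazard", "recurrence_prob",
                     "crossover_prob", "selfharm_prob", "suicide_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        self.onset.validate()
        for k, v in self.comorbidities.items():
            v.validate(k)
        if self.treatment is not None:
            self.treatment.validate()

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.c2

    def sex_specific_risks(self) -> tuple[float, float]:
        """(K_female, K_male) such that K_f/K_m = female_male_rr and mean is K."""
        K, rr = self.lifetime_risk_by_49, self.female_male_rr
        k_m = 2.0 * K / (1.0 + rr)
        return rr * k_m, k_m

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "onset" in d and isinstance(d["onset"], dict):
            o = dict(d["onset"])
            if "support" in o:
                o["support"] = tuple(o["support"])
            d["onset"] = OnsetModel(**o)
        if "comorbidities" in d:
            com = {}
            for k, v in d["comorbidities"].items():
                if isinstance(v, dict):
                    v = dict(v)
                    if isinstance(v.get("onset"), dict):
                        o = dict(v["onset"])
                        if "support" in o:
                            o["support"] = tuple(o["support"])
                        v["onset"] = OnsetModel(**o)
                    v = Comorbidity(**v)
                com[k] = v
            d["comorbidities"] = com
        if isinstance(d.get("treatment"), dict):
            d["treatment"] = TreatmentParams(**d["treatment"])
        for key in ("birth_year_range", "register_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def broad_preset(**overrides) -> SimConfig:
    """Births 1965-2000, followed to age 49 within a 1975-2013 register."""
    cfg = SimConfig(birth_year_range=(1965, 2000), register_window=(1975, 2013))
    return dataclasses.replace(cfg, **overrides)


def narrow_preset(**overrides) -> SimConfig:
    """Births 1985-2000, followed to age 29 within a 1995-2013 register."""
    cfg = SimConfig(birth_year_range=(1985, 2000), register_window=(1995, 2013))
    return dataclasses.replace(cfg, **overrides)


@dataclass
class CohortSpec:
    """Register cohort-selection rules.

    Applied in a fixed order: birth-year window, born-in-country, minimum
    diagnosis age (cases first diagnosed younger are dropped entirely), and a
    minimum follow-up after first diagnosis (cases only; suicide deaths are
    retained when ``keep_suicide_deaths``).
    """

    birth_year_range: tuple[int, int] = (1965, 2000)
    min_diagnosis_age: float = 10.0
    min_followup_after_first_dx: float = 5.0
    require_born_in_country: bool = True
    keep_suicide_deaths: bool = True
    age_cap: float = 49.0
    care_settings: Optional[tuple[str, ...]] = None  # None = all settings

    def validate(self) -> None:
        if self.min_diagnosis_age < 0:
            raise ValueError("min_diagnosis_age must be >= 0")
        if self.age_cap <= self.min_diagnosis_age:
            raise ValueError("age_cap must exceed min_diagnosis_age")
        if self.min_followup_after_first_dx < 0:
            raise ValueError("min_followup_after_first_dx must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("birth_year_range", "care_settings"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)
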