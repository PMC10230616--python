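"""Sibling-based liability-scale heritability.

Two estimators, sharing the liability-threshold model (a standard-normal
latent liability; persons above the threshold t = Phi^-1(1 - K) are affected):

1. Falconer-type conversion of population risk and the risk in relatives of
   affected persons into liability-scale heritability, with the
   Reich-James-Morris correction available, and a weighted mean across strata.
2. A maximum-likelihood ACE threshold model on full and maternal-half sibling
   pairs: pair liability correlation a_R*h2 + c2 (a_R = 0.5 full / 0.25
   maternal half, shared environment fully shared by both), person-specific
   thresholds shifted by sex, standardized birth year and its square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .bvn import bvn_orthant
from .registry import Cohort

__all__ = ["build_sib_pairs", "liability_threshold", "falconer_h2",
           "weighted_mean_h2", "fit_ace", "sibling_stratified_risks",
           "falconer_from_pairs", "HeritabilityEstimate", "FalconerComponent"]

RELATEDNESS = {"full": 0.5, "maternal_half": 0.25}


# ---------------------------------------------------------------------------
# sibling pairs
# ---------------------------------------------------------------------------

def build_sib_pairs(cohort: Cohort) -> pd.DataFrame:
    """All unordered within-cohort sibling pairs sharing a mother.

    Pairs with the same (known) father are ``full``; pairs with different
    known fathers are ``maternal_half``.  Pairs where either father is unknown
    are dropped.  A sibship of size s contributes s(s-1)/2 pairs.
    """
    m = cohort.members.reset_index()
    m = m.rename(columns={m.columns[0]: "person_id"})
    cols = ["person_id", "mother_id", "father_id", "is_case", "sex", "birth_year"]
    sibs = m.loc[m["mother_id"].notna(), cols]
    merged = sibs.merge(sibs, on="mother_id", suffixes=("_a", "_b"))
    merged = merged[merged["person_id_a"] < merged["person_id_b"]]
    both_known = merged["father_id_a"].notna() & merged["father_id_b"].notna()
    merged = merged[both_known]
    full = merged["father_id_a"] == merged["father_id_b"]
    pairs = pd.DataFrame({
        "person_a": merged["person_id_a"].to_numpy(),
        "person_b": merged["person_id_b"].to_numpy(),
        "relation": np.where(full, "full", "maternal_half"),
        "case_a": merged["is_case_a"].to_numpy(dtype=bool),
        "case_b": merged["is_case_b"].to_numpy(dtype=bool),
        "sex_a": merged["sex_a"].to_numpy(),
        "sex_b": merged["sex_b"].to_numpy(),
        "by_a": merged["birth_year_a"].to_numpy(dtype=float),
        "by_b": merged["birth_year_b"].to_numpy(dtype=float),
    })
    pairs["a_R"] = pairs["relation"].map(RELATEDNESS)
    return pairs.reset_index(drop=True)


def sample_one_pair_per_sibship(pairs: pd.DataFrame, cohort: Cohort,
                                seed: int = 0) -> pd.DataFrame:
    """Optionally thin to one pair per mother-sibship (independence of pairs)."""
    mother = cohort.members["mother_id"]
    key = pairs["person_a"].map(mother)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return pairs.iloc[order].groupby(key.iloc[order].to_numpy()).head(1) \
        .sort_index().reset_index(drop=True)


# ---------------------------------------------------------------------------
# Falconer-type estimation
# ---------------------------------------------------------------------------

def liability_threshold(K: float) -> tuple[float, float]:
    """Threshold t = Phi^-1(1-K) and mean liability of the affected i = phi(t)/K."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"K must be in (0,1), got {K}")
    t = stats.norm.isf(K)
    i = stats.norm.pdf(t) / K
    return float(t), float(i)


@dataclass
class FalconerComponent:
    h2: float
    se: Optional[float]
    K_pop: float
    K_rel: float
    a_R: float
    variant: str
    stratum: str = ""
    clipped: bool = False


def _falconer_point(K_pop: float, K_rel: float, a_R: float, variant: str) -> float:
    t_pop, i_pop = liability_threshold(K_pop)
    t_rel, _ = liability_threshold(K_rel)
    if variant == "falconer":
        b = (t_pop - t_rel) / i_pop
    elif variant == "reich":
        inner = 1.0 - (t_pop**2 - t_rel**2) * (1.0 - t_pop / i_pop)
        b = (t_pop - t_rel * np.sqrt(max(inner, 0.0))) \
            / (i_pop + t_rel**2 * (i_pop - t_pop))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return b / a_R


def falconer_h2(K_pop: float, K_rel: float, a_R: float = 0.5,
                variant: str = "falconer",
                K_pop_ci: Optional[tuple[float, float]] = None,
                K_rel_ci: Optional[tuple[float, float]] = None,
                stratum: str = "") -> FalconerComponent:
    """Liability-scale heritability from population and relative risks.

    ``variant="falconer"``: h2 = (t_pop - t_rel) / (a_R * i_pop).
    ``variant="reich"``: the Reich-James-Morris corrected regression of
    relative liability on proband liability, divided by a_R.
    Delta-method SEs are produced when 95% CIs for the Ks are supplied.
    """
    if a_R not in (0.25, 0.5):
        raise ValueError("a_R must be 0.25 (maternal half) or 0.5 (full)")
    if not 0.0 < K_rel < 1.0:
        raise ValueError("degenerate relative stratum: K_rel outside (0,1)")
    h2 = _falconer_point(K_pop, K_rel, a_R, variant)
    se = None
    if K_pop_ci is not None and K_rel_ci is not None:
        se_p = (K_pop_ci[1] - K_pop_ci[0]) / 3.92
        se_r = (K_rel_ci[1] - K_rel_ci[0]) / 3.92
        eps_p, eps_r = max(1e-6, se_p / 10), max(1e-6, se_r / 10)
        dp = (_falconer_point(K_pop + eps_p, K_rel, a_R, variant)
              - _falconer_point(K_pop - eps_p, K_rel, a_R, variant)) / (2 * eps_p)
        dr = (_falconer_point(K_pop, K_rel + eps_r, a_R, variant)
              - _falconer_point(K_pop, K_rel - eps_r, a_R, variant)) / (2 * eps_r)
        se = float(np.sqrt((dp * se_p)**2 + (dr * se_r)**2))
    clipped = not 0.0 <= h2 <= 1.0
    return FalconerComponent(float(np.clip(h2, 0.0, 1.0)) if clipped else float(h2),
                             se, K_pop, K_rel, a_R, variant, stratum, clipped)


def weighted_mean_h2(components: list[FalconerComponent],
                     weighting: str = "inverse_variance",
                     sizes: Optional[list[float]] = None) -> tuple[float, float]:
    """Pool per-stratum estimates: inverse-variance (default) or sample-size
    weights.  Returns (pooled h2, pooled SE)."""
    if not components:
        raise ValueError("need at least one stratum")
    h = np.array([c.h2 for c in components])
    if weighting == "inverse_variance":
        if any(c.se is None or c.se <= 0 for c in components):
            raise ValueError("inverse-variance weighting needs positive SEs")
        w = np.array([1.0 / c.se**2 for c in components])
        return float(np.sum(w * h) / np.sum(w)), float(np.sqrt(1.0 / np.sum(w)))
    if weighting == "sample_size":
        if sizes is None or len(sizes) != len(components):
            raise ValueError("sample_size weighting needs one size per stratum")
        w = np.asarray(sizes, dtype=float)
        pooled = float(np.sum(w * h) / np.sum(w))
        ses = np.array([c.se if c.se is not None else 0.0 for c in components])
        se = float(np.sqrt(np.sum(w**2 * ses**2)) / np.sum(w))
        return pooled, se
    raise ValueError(f"unknown weighting {weighting!r}")


def sibling_stratified_risks(pairs: pd.DataFrame, relation: str = "full",
                             by_sex: bool = False) -> pd.DataFrame:
    """Person-level risks by sibling exposure (>=1 affected sibling of the
    given relation, fixed over the register window).

    Returns one row per stratum with K_pop (all persons in such pairs),
    K_exposed, K_unexposed, and counts.
    """
    sub = pairs[pairs["relation"] == relation]
    long = pd.concat([
        sub.rename(columns={"person_a": "person", "case_a": "case", "sex_a": "sex",
                            "case_b": "sib_case"})[["person", "case", "sex", "sib_case"]],
        sub.rename(columns={"person_b": "person", "case_b": "case", "sex_b": "sex",
                            "case_a": "sib_case"})[["person", "case", "sex", "sib_case"]],
    ])
    per = long.groupby("person").agg(case=("case", "first"), sex=("sex", "first"),
                                     exposed=("sib_case", "any"))
    strata = per.groupby("sex") if by_sex else [("all", per)]
    rows = []
    for label, g in strata:
        exposed = g[g["exposed"]]
        unexposed = g[~g["exposed"]]
        rows.append({
            "stratum": label, "relation": relation,
            "n": len(g), "n_exposed": len(exposed),
            "K_pop": g["case"].mean(),
            "K_exposed": exposed["case"].mean() if len(exposed) else np.nan,
            "K_unexposed": unexposed["case"].mean() if len(unexposed) else np.nan,
        })
    return pd.DataFrame(rows)


def _prop_ci(p: float, n: int) -> tuple[float, float]:
    se = np.sqrt(max(p * (1 - p), 1e-12) / max(n, 1))
    return max(p - 1.96 * se, 1e-9), min(p + 1.96 * se, 1 - 1e-9)


def falconer_from_pairs(pairs: pd.DataFrame, relation: str = "full",
                        variant: str = "falconer", by_sex: bool = True,
                        weighting: str = "inverse_variance") -> "HeritabilityEstimate":
    """Falconer-type heritability from sibling pairs: population risk vs risk
    in persons with >=1 affected sibling, optionally within sex strata pooled
    by ``weighted_mean_h2`` (sex stratification avoids the single-threshold
    misspecification when lifetime risk differs by sex)."""
    risks = sibling_stratified_risks(pairs, relation, by_sex=by_sex)
    a_R = RELATEDNESS[relation]
    comps, sizes = [], []
    for _, row in risks.iterrows():
        if not 0 < row["K_exposed"] < 1 or not 0 < row["K_pop"] < 1:
            continue
        comps.append(falconer_h2(
            row["K_pop"], row["K_exposed"], a_R, variant,
            K_pop_ci=_prop_ci(row["K_pop"], row["n"]),
            K_rel_ci=_prop_ci(row["K_exposed"], row["n_exposed"]),
            stratum=str(row["stratum"])))
        sizes.append(row["n_exposed"])
    if not comps:
        raise ValueError("no usable strata (degenerate exposed risks)")
    h2, se = weighted_mean_h2(comps, weighting,
                              sizes if weighting == "sample_size" else None)
    clipped = not 0.0 <= h2 <= 1.0
    return HeritabilityEstimate(
        h2=float(np.clip(h2, 0, 1)), c2=np.nan, e2=np.nan, se_h2=se, se_c2=None,
        method="falconer_incidence", converged=True, boundary=False,
        clipped=clipped, n_pairs=int(len(pairs)),
        extras={"components": comps, "risks": risks, "variant": variant,
                "weighting": weighting})


# ---------------------------------------------------------------------------
# maximum-likelihood ACE threshold model
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    """Variance-component estimate on the liability scale."""

    h2: float
    c2: float
    e2: float
    se_h2: Optional[float]
    se_c2: Optional[float]
    method: str
    tau: Optional[float] = None
    beta: Optional[dict[str, float]] = None
    loglik: Optional[float] = None
    converged: bool = True
    boundary: bool = False
    clipped: bool = False
    n_pairs: int = 0
    extras: dict = field(default_factory=dict)


_ACE_STARTS = ((0.3, 0.1), (0.6, 0.05), (0.05, 0.3))


def ace_negloglik(theta: np.ndarray, design: dict, nodes: int = 24) -> float:
    """Negative log-likelihood of the pairwise ACE threshold model.

    ``design`` holds per-pair covariate arrays (see :func:`fit_ace`).  Exposed
    for oracle tests: at h2 = c2 = 0 it reduces to independent Bernoulli terms.
    """
    h2, c2, tau, bs, b1, b2 = theta
    h2c, c2c = max(h2, 0.0), max(c2, 0.0)
    t_a = tau - (bs * design["sex_a"] + b1 * design["by_a"] + b2 * design["by2_a"])
    t_b = tau - (bs * design["sex_b"] + b1 * design["by_b"] + b2 * design["by2_b"])
    P11 = np.empty(len(t_a))
    for mask, a_R in ((design["full"], 0.5), (~design["full"], 0.25)):
        if mask.any():
            r = min(a_R * h2c + c2c, 0.999)
            P11[mask] = bvn_orthant(t_a[mask], t_b[mask], r, nodes=nodes)
    Pa, Pb = ndtr(-t_a), ndtr(-t_b)
    ca, cb = design["case_a"], design["case_b"]
    p = np.where(ca & cb, P11,
                 np.where(ca & ~cb, Pa - P11,
                          np.where(~ca & cb, Pb - P11, 1.0 - Pa - Pb + P11)))
    return float(-np.sum(design["w"] * np.log(np.clip(p, 1e-300, 1.0))))


def _make_design(pairs: pd.DataFrame) -> dict:
    """Per-pair covariate arrays, deduplicated with multiplicity weights.

    The pair likelihood is invariant under swapping members, so each pair is
    canonicalised (member with the lexicographically smaller covariate tuple
    first) and identical (relation, covariates, pattern) rows collapse into a
    single weighted row: the likelihood value is unchanged while large cohorts
    with integer birth years shrink by orders of magnitude.
    """
    by_all = np.concatenate([pairs["by_a"], pairs["by_b"]])
    mu, sd = by_all.mean(), by_all.std() or 1.0
    za = (pairs["by_a"].to_numpy() - mu) / sd
    zb = (pairs["by_b"].to_numpy() - mu) / sd
    sex_a = (pairs["sex_a"] == "F").to_numpy(dtype=np.int8)
    sex_b = (pairs["sex_b"] == "F").to_numpy(dtype=np.int8)
    ca = pairs["case_a"].to_numpy(dtype=np.int8)
    cb = pairs["case_b"].to_numpy(dtype=np.int8)
    full = (pairs["relation"] == "full").to_numpy(dtype=np.int8)

    swap = (sex_a > sex_b) | ((sex_a == sex_b) & (za > zb)) \
        | ((sex_a == sex_b) & (za == zb) & (ca > cb))
    sex_a2 = np.where(swap, sex_b, sex_a)
    sex_b2 = np.where(swap, sex_a, sex_b)
    za2 = np.where(swap, zb, za)
    zb2 = np.where(swap, za, zb)
    ca2 = np.where(swap, cb, ca)
    cb2 = np.where(swap, ca, cb)

    key = np.rec.fromarrays([full, sex_a2, sex_b2, za2, zb2, ca2, cb2])
    uniq, counts = np.unique(key, return_counts=True)
    return {
        "sex_a": uniq.f1.astype(float), "sex_b": uniq.f2.astype(float),
        "by_a": uniq.f3, "by_b": uniq.f4,
        "by2_a": uniq.f3**2, "by2_b": uniq.f4**2,
        "case_a": uniq.f5.astype(bool), "case_b": uniq.f6.astype(bool),
        "full": uniq.f0.astype(bool),
        "w": counts.astype(float),
    }


def fit_ace(pairs: pd.DataFrame, nodes: int = 24,
            compute_se: bool = True) -> HeritabilityEstimate:
    """Maximum-likelihood ACE threshold model on sibling pairs.

    Pair liability correlation is a_R*h2 + c2; person thresholds are
    tau - (beta_sex*sex + beta_by*by + beta_by2*by^2) with birth year
    standardized (the square computed post-standardization).  Parameters
    maximize the summed pair log-likelihoods subject to h2, c2 >= 0 and
    h2 + c2 <= 1, from three fixed starting points.  SEs come from a central
    -difference Hessian; boundary solutions are flagged.
    """
    if not len(pairs):
        raise ValueError("no sibling pairs")
    relations = set(pairs["relation"])
    identifiable = relations >= {"full", "maternal_half"}
    if not identifiable:
        warnings.warn("only one relation class present: A and C are not "
                      "separately identifiable", stacklevel=2)
    design = _make_design(pairs)
    K0 = float(np.mean(np.concatenate([design["case_a"], design["case_b"]])))
    tau0 = stats.norm.isf(min(max(K0, 1e-4), 1 - 1e-4))

    bounds = [(0.0, 1.0), (0.0, 1.0), (-5.0, 5.0),
              (-3.0, 3.0), (-3.0, 3.0), (-3.0, 3.0)]
    cons = [{"type": "ineq", "fun": lambda th: 1.0 - th[0] - th[1]}]

    best = None
    for h2_0, c2_0 in _ACE_STARTS:
        x0 = np.array([h2_0, c2_0, tau0, 0.0, 0.0, 0.0])
        res = optimize.minimize(ace_negloglik, x0, args=(design, nodes),
                                method="SLSQP", bounds=bounds, constraints=cons,
                                options={"maxiter": 200, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    h2, c2, tau, bs, b1, b2 = best.x
    boundary = h2 < 1e-4 or c2 < 1e-4 or (h2 + c2) > 1 - 1e-4

    se_h2 = se_c2 = None
    cov = None
    if compute_se:
        try:
            H = _numerical_hessian(lambda th: ace_negloglik(th, design, nodes), best.x)
            cov = np.linalg.pinv(H)
            d = np.diag(cov)
            if (d[:2] >= 0).all():
                se_h2, se_c2 = float(np.sqrt(d[0])), float(np.sqrt(d[1]))
        except Exception:                      # singular Hessian at a boundary
            pass

    return HeritabilityEstimate(
        h2=float(h2), c2=float(c2), e2=float(1.0 - h2 - c2),
        se_h2=se_h2, se_c2=se_c2, method="ace_ml", tau=float(tau),
        beta={"sex": float(bs), "birth_year": float(b1), "birth_year_sq": float(b2)},
        loglik=float(-best.fun), converged=bool(best.success),
        boundary=boundary, n_pairs=int(len(pairs)),
        extras={"identifiable": identifiable, "cov": cov,
                "optimizer_message": best.message})


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    fx = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            if i == j:
                H[i, i] = (f(x + ei) - 2 * fx + f(x - ei)) / eps**2
            else:
                H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                     - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps**2)
    return H
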