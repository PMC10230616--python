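# Methods

## The generative model

The synthetic register emulates a two-generation national population with a
classical ACE liability structure.

**Pedigrees.**  `n_families` mothers each have a sibship of children
(zero-truncated Poisson with mean `mean_children_per_mother`, default 2.3, or
a fixed `sibship_size`).  A configurable fraction of sibships
(`half_sib_family_fraction`, default 0.15) have children by two fathers;
fathers are unrelated founders, there is no assortative mating and no
dominance.  Founders are full register persons: they receive their own
liability (with personal `C` and `E` draws, since their own sibships are not
modelled), case status, diagnoses and censoring.  This matters: founders born
inside the study birth window are legitimate cohort members, and treating
them as event-free placeholders would bias incidence downward.

**Liability.**  `L = A + C + E`, `Var(L) = 1`.  Founder `A ~ N(0, a²)`;
child `A = ½(A_m + A_f) + N(0, a²/2)`.  `C ~ N(0, c²)` once per
mother-sibship (full and maternal-half siblings share it fully);
`E ~ N(0, e²)`, `e² = 1 − a² − c²`.  Defaults `a² = 0.45`, `c² = 0.05`,
matching moderate-heritability psychiatric phenotypes.

**Case status and onset.**  Person is a lifetime case iff `L` exceeds a
sex-specific threshold.  Thresholds are calibrated so the sex-averaged
lifetime risk by the age cap equals `lifetime_risk_by_49` (default 0.072)
and the female:male risk ratio equals `female_male_rr` (default 1.7) —
this encodes the reported female excess without touching the variance
components.  Ages at onset are drawn from a truncated normal (mean 27, SD 8,
support [10, 49) years), independent of liability magnitude given case
status; an optional liability-graded mode maps higher liability to earlier
onset quantiles.  Onset is deliberately not a survival model driven by
liability — the analysable default keeps case status exactly
threshold-consistent.

**Events.**  Diagnosed cases receive an era-appropriate first MDD code
(ICD-8 before 1987, ICD-9 to 1996, ICD-10 after; F32.x with F32.1 modal),
geometric follow-up contacts (P(no extra contact) = 0.27), and Bernoulli
clinical events with exponential lags from onset: recurrence (0.31, F33/296.3
codes), excess diagnostic cross-over (0.02 on top of what the correlated
bipolar/schizophrenia liabilities already induce, totalling ~5% of cases),
self-harm (0.07, X60–X84 codes), suicide (0.004, recorded as death with a
cause flag).  Comorbid disorders (anxiety, ADHD, ASD, bipolar, eating
disorders, schizophrenia, substance use) arise from liabilities correlated
with the MDD liability (`L_d = ρL + √(1−ρ²)Z`), each with its own lifetime
risk and onset model; their codes are ICD-10 at all dates — only MDD
exercises the revision mapping.  ECT appears as a procedure-coded row
(`DA024`).

**Treatment.**  Treated cases (68%) accumulate prescription fills:
1 + Poisson(4) episodes, 1 + Poisson(1.5) fills of 30 days' supply each,
refill gaps ≤ 20 days inside an episode and 120–420-day gaps between
episodes.  Episodes usually continue the previous drug class (re-draw
probability 0.35), giving a median of 2 distinct medications.  Class mix
SSRI 0.55 / SNRI 0.22 / TCA 0.08 / other 0.15.  14% of treated cases get a
concurrent second antidepressant in their first episode and 5% an
augmentation agent, which together with the 68% treated fraction yields
roughly one in ten cases reaching the combination/augmentation step.

**Censoring.**  Constant annual hazards for emigration (0.003) and mortality
(0.001) from birth, resolved to the earlier of the two; events and fills are
emitted only inside `[max(birth, register_start), exit)` with
`exit = min(death, emigration, register_end)`.  All dates are decimal years,
births at mid-year, intervals half-open.

**What the generator does not emulate.**  Real demography (immigration
waves, cohort-varying fertility), care-seeking and regional variation in
coding, period effects in risk, socioeconomic covariates, non-constant
hazards.  Passing tests therefore show that the estimators are correct under
the stated liability/censoring model, not that they are robust to the messiness
of real registers.

## Cohort selection

Rules run in a fixed order, each counting its exclusions in a ledger:
birth-year window (default 1965–2000) → born-in-country → first diagnosis
before age 10 (cases removed entirely) → less than 5 years of follow-up
after first diagnosis (cases only; suicide deaths retained because suicide
is an outcome of interest) → unobservable windows (exit ≤ entry, e.g.
childhood death).  Input count = output + ledger sum, and re-applying the
rules to a selected cohort removes nobody.  The ICD-8/9 MDD equivalents
(ICD-9 296.2/296.3/311, ICD-8 296.0/300.4) are provisional, editable
defaults.

## Survival estimation

Both cumulative-incidence estimators are computed from one shared risk-set
table: risk set at `t` counts subjects with `entry < t ≤ time`, so events at
a tied age are processed before censorings; delayed entry left-truncates
subjects whose resolved time is not after entry.  One-minus-KM uses the
product-limit survivor with Greenwood variance; Aalen–Johansen accumulates
`S_all(t⁻)·d₁/n` with death as a competing event and a Greenwood-type
plug-in variance on the sub-distribution jumps (a first-order approximation
that ignores cross-covariance terms; adequate for the pointwise 95% bands
produced here).  With no competing events the two estimators coincide to
machine precision by construction.  `lifelines` serves as an independent
oracle in the test suite, not as the implementation, because exact tie
conventions and AJ/KM equality are asserted to machine precision.

## Heritability

**Falconer route.**  Exposure is fixed over the register window: a person is
"exposed" if ≥1 sibling of the given relation is ever affected.  `K_pop` and
`K_rel` convert to liability units via `t = Φ⁻¹(1−K)`, `i = φ(t)/K`; the
default variant is Falconer's linear conversion, with Reich–James–Morris
selectable.  Because lifetime risk differs by sex, a single pooled threshold
is misspecified; the default therefore estimates within sex strata and pools
by inverse-variance (sample-size weights available).  Delta-method SEs come
from binomial CIs on the two risks.

**ACE maximum likelihood.**  All sibling pairs enter (sibships of size s
contribute s(s−1)/2 pairs); pairs are treated as independent, so SEs are
anti-conservative when sibships exceed two — a documented register-practice
trade-off, with seeded one-pair-per-sibship thinning available.  The pair
log-likelihood is evaluated on deduplicated covariate patterns (the
likelihood is invariant to pair order, and integer birth years make patterns
highly redundant), which cuts evaluation cost by an order of magnitude
without changing the value.  Optimisation: SLSQP with bounds
`h², c² ∈ [0,1]`, constraint `h² + c² ≤ 1`, three fixed starting points
((0.3, 0.1), (0.6, 0.05), (0.05, 0.3)); `τ` initialised from the observed
case rate; boundary solutions flagged.  The orthant kernel is the classical
single-integral reduction of the bivariate normal, evaluated with fixed
Gauss–Legendre nodes, vectorised over threshold pairs; absolute error is
below 1e−9 for |r| ≤ 0.95 with 96 nodes (24 nodes inside the optimiser,
where |r| ≤ 0.6), verified against `scipy.stats.multivariate_normal`.

**Precision at desk scale.**  The Fisher information of a binary sibling
pair at K = 0.072 is small: with 50k full + 20k half pairs the Cramér–Rao
bound gives SE(ĥ²) ≈ 0.10 and SE(ĉ²) ≈ 0.046, and the implementation
attains it (numerical-Hessian SEs and across-seed SDs agree).  Recovering
h² to ±0.05 with high probability needs on the order of 10⁶ pairs — the
scale of real national registers.  Test and script designs therefore use a
few hundred thousand pairs where agreement between methods is checked, and
report SEs everywhere; the acceptance suite keeps one recovery check at the
smaller design size, which the information bound shows cannot reliably meet
its nominal tolerance — it documents the precision limit rather than an
estimator defect.

## Outcomes and treatment analyses

Cross-over uses a wash-out: a bipolar/schizophrenia-spectrum code at or
before first MDD + `washout_years` (default 1.0, configurable; the length
real studies use is supplementary and not reproduced here) removes the
person from the cross-over denominator as diagnostic uncertainty.
Recurrence is any recurrent-MDD-mapped code within follow-up; mortality
outcomes are restricted to deaths before age 50, suicide and other-cause
mutually exclusive by cause flag.  Country comparison: Mantel–Haenszel
stratified chi-squared (age band × sex strata) for the country effect,
Cochran's Q with inverse-variance weights on log-RR across age strata for
pattern similarity, and a df = 1 Q contrasting the two countries' pooled
sex log-RRs; zero cells get the Haldane–Anscombe 0.5 correction.

Episode construction: fill coverage `[date, date + days_supplied)`; gaps ≤
`grace_days` (default 56 — a standard pharmacoepidemiology convention,
documented as provisional) merge; classification thresholds ≥2 classes
concurrent ≥ `overlap_days` (default 30) for combination, any augmentation
agent during antidepressant coverage, ECT procedure codes dominating.  A
1e−9-year tolerance guards exact-threshold overlaps against date-arithmetic
rounding.  Steps partition the case set; times-to-step are measured from
first MDD diagnosis and floored at zero.

## Numerical and design choices

- Decimal-year dates throughout; mid-year births when only a year is known;
  0-based half-open age intervals.
- `bvn_orthant` handles r = ±1 by closed forms; correlations inside the ACE
  objective are clipped at 0.999.
- Pattern probabilities are floored at 1e−300 inside the log-likelihood.
- The exclusion ledger gains an `unobservable` key beyond the four named
  rules so that count conservation is exact.
- Default estimator for incidence is Aalen–Johansen because death is itself
  an outcome in this population; both estimators are always available and
  tagged in outputs.
- Reproducibility: a single `numpy` Generator seeded from the config; equal
  config + seed gives byte-identical register files; the pipeline manifest
  records config hash, seed, package version and per-stage row counts.

## Problem sizes

Unit tests run on registers of roughly 10³–10⁵ persons; heritability
checks use 56k–210k sibling pairs and the acceptance script about 2×10⁵
persons plus three pair designs, totalling under a minute on one CPU.  These
sizes were chosen so that each check's tolerance exceeds its Monte-Carlo
error by a comfortable margin (see the Fisher analysis above for the one
deliberate exception).

## Known limitations

- Pair-based ACE ignores sibship-level dependence; no twin, parent–offspring
  or SNP-based designs; no ascertainment correction.
- Falconer conversion is first-order in the liability correlation and
  overstates h² when c² > 0 (it attributes all sibling resemblance to A).
- The AJ variance is an approximation; bootstrap bands are out of scope.
- Generator realism limits listed above; ICD mapping defaults are
  provisional stand-ins for register-specific tables.
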