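"""Bidirectional comorbidity trajectories around the first MDD diagnosis.

direction="before": among persons with a comorbid disorder, the cumulative
incidence of MDD from that disorder's onset.  direction="after": among MDD
cases, the cumulative incidence of each comorbid disorder after MDD onset.
"""

import liabreg as lr

bundle = lr.simulate_registry(lr.broad_preset(n_families=20000, seed=5))
cohort = lr.select_cohort(
    bundle, lr.CohortSpec(min_followup_after_first_dx=0), lr.default_code_map())
code_map = lr.default_code_map()
disorders = ["anxiety", "adhd", "bipolar"]

for direction, label in (("before", "MDD after disorder"),
                         ("after", "disorder after MDD")):
    curves = lr.comorbidity_trajectories(cohort, bundle.diagnoses, code_map,
                                         other_disorders=disorders,
                                         direction=direction)
    print(f"--- {label} (cumulative incidence by 49) ---")
    for d, c in curves.items():
        print(f"  {d:10s} {c.at(49):.3f}")

pop = lr.cumulative_incidence(cohort, estimator="one_minus_km")
print(f"population MDD incidence by 49: {pop.at(49):.3f}")
print("liability correlations make MDD risk after anxiety/ADHD exceed the "
      "population baseline, mirroring register comorbidity patterns")
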