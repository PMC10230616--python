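"""Clinical outcomes with the cross-over wash-out rule, treatment contacts,
antidepressant episodes and intensification trajectories."""

import liabreg as lr

bundle = lr.simulate_registry(lr.broad_preset(n_families=20000, seed=9))
code_map = lr.default_code_map()
cohort = lr.select_cohort(bundle, lr.CohortSpec(), code_map)

rates = lr.clinical_outcomes(cohort, bundle.diagnoses, code_map,
                             washout_years=1.0)
print("outcome rates among MDD cases:")
print(rates[rates["sex"] == "all"]
      [["outcome", "numerator", "denominator", "proportion"]]
      .to_string(index=False))

contacts = lr.treatment_contacts(cohort, bundle.diagnoses, code_map)
out = contacts["specialist_outpatient"]
print(f"\nspecialist outpatient contacts: median {out['median']:.0f} "
      f"(IQR {out['iqr']:.0f}), {out['pct_single_contact']:.1f}% single-contact")
print(f"ever inpatient: {contacts['pct_ever_inpatient']:.1f}%")

episodes, summaries = lr.build_episodes(bundle.fills, grace_days=56)
print(f"\nantidepressant users: {len(summaries)}; "
      f"mean episodes {summaries['n_episodes'].mean():.1f}; "
      f"mean months on drug {summaries['total_months'].mean():.1f}")

traj = lr.classify_trajectories(cohort, bundle.fills, bundle.diagnoses,
                                code_map, overlap_days=30, grace_days=56)
print("\nintensification trajectory (share of cases):")
print(lr.trajectory_summary(traj)
      [["step", "pct_of_cases", "median_years_to_step"]]
      .to_string(index=False))
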