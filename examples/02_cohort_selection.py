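"""Apply register cohort-selection rules and inspect the exclusion ledger.

Rules (fixed order): birth cohort 1965-2000; born in-country; cases first
diagnosed before age 10 removed; cases with under 5 years of follow-up after
first diagnosis removed (suicide deaths retained); unobservable windows.
"""

import liabreg as lr

bundle = lr.simulate_registry(lr.broad_preset(n_families=5000, seed=7))
cohort = lr.select_cohort(bundle, lr.CohortSpec(), lr.default_code_map())

print("input persons: ", len(bundle.persons))
print("cohort members:", len(cohort))
print("exclusions per rule:")
for rule, n in cohort.ledger.items():
    print(f"  {rule:18s} {n:6d}")
print("cases in cohort:", int(cohort.members['is_case'].sum()))

# every excluded person is accounted for exactly once
assert len(bundle.persons) == len(cohort) + sum(cohort.ledger.values())
print("ledger conservation holds")
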