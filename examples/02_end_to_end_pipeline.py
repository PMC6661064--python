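"""Simulate a claims cohort and run the full ascertainment pipeline.

Run:  python examples/02_end_to_end_pipeline.py
"""

from claimcase import (
    SimParams,
    StudyConfig,
    expected_cases,
    generate_cohort,
    run_pipeline,
)

config = StudyConfig()
params = SimParams(n_patients=2000, seed=42)
claims, truth = generate_cohort(params, config)
print(f"generated {len(claims)} claims for {params.n_patients} patients "
      f"({len(truth.events)} planted fracture events)")

cases, linkage = run_pipeline(claims, config)
print(f"linkage consolidated the claims into {linkage.n_patients} patients")
print(f"pipeline accepted {len(cases)} first-incidence fracture cases")

oracle = expected_cases(truth, config)
print(f"planted-truth oracle expects {len(oracle)} cases; "
      f"exact match: {set(cases) == set(oracle)}")

# The gap between planted events and accepted cases is by design: events
# flagged hospital-acquired, suspected-only or out-of-region must be excluded,
# and first visits resolving outside the case window are not counted.
excluded = sum(
    ev.hospital_acquired or ev.suspected_only or ev.out_of_region
    for ev in truth.events
)
print(f"({excluded} planted events carry an exclusion flag)")
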