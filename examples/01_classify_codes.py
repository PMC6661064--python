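"""Classify ICD-10 injury codes into fracture site groups.

Run:  python examples/01_classify_codes.py
"""

from claimcase import classify_site, is_fracture_procedure

codes = ["S52.5", "S42.0", "S82.6", "S82.5", "S72.0", "S22.3", "S52.50", "M80.0"]
print("ICD-10 code -> fracture site group")
for code in codes:
    group = classify_site(code)
    print(f"  {code:8s} -> {group.label if group else '(not a tracked fracture site)'}")

print("\nprocedure code -> counts toward case ascertainment?")
for code in ["K044", "K046-2", "K082", "K047"]:
    print(f"  {code:8s} -> {is_fracture_procedure(code)}")

# A distal radius code (S52.5) and an ankle code (S82.6) land in their own
# groups; S22.3 (rib) is tracked under the rib/sternum group; M80.0
# (osteoporotic fracture) is deliberately outside the case definition, and
# K047 is not one of the nine fracture-specific treatment procedures.
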