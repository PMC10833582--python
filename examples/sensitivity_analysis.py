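"""Stepwise one-way deterministic sensitivity analysis (DSA).

Each model input is varied one at a time from -30% to +30% in 10% steps
and every patent year is repriced.  The eligible patient population is the
most influential input: it sits in the denominator of the amortization, so
shrinking it by 30% raises the launch price by over 40%.
"""

from cbpricer import DsaSpec, dsa_range, dsa_stepwise, packaged_population, packaged_profile

pop = packaged_population()

for drug in ("daratumumab", "pembrolizumab"):
    profile = packaged_profile(drug)
    print(f"\n{drug}: per-vial price range over all years and steps (EUR)")
    for input_name in ("eligible_patients", "initial_rd", "profit_margin", "manufacturing_per_gram"):
        table = dsa_stepwise(profile, DsaSpec(input_name), pop)
        lo, hi = dsa_range(table)
        print(f"  {input_name:<24} {lo:>10,.2f} - {hi:>12,.2f}")

print(
    "\nThe maxima occur at the launch year with patients at -30% (or costs"
    "\nat +30%); the minima at the cheapest base-case year with the opposite"
    "\nstep. At step 1.0 the DSA reproduces the base case exactly."
)
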