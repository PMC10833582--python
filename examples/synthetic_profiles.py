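"""Synthetic drug profiles: stress-testing the model beyond the case studies.

The generator produces structurally valid multi-indication profiles (a
pure function of the seed) so pricing behaviour can be explored across
many hypothetical drugs without any external data.
"""

from cbpricer import SyntheticSpec, flat_population, price_series, synthetic_profile

pop = flat_population(10_000_000.0, 2000, 2045)

for seed in (1, 2, 3):
    profile = synthetic_profile(SyntheticSpec(seed=seed, n_indications=3))
    series = price_series(profile, pop, "year")
    print(
        f"seed {seed}: {profile.name} launch {profile.launch_year}, "
        f"expiry {profile.patent_expiry}, vial {profile.vial_grams:.2f} g"
    )
    print(
        f"  per-vial price: {series.per_vial.iloc[0]:>12,.2f} EUR at launch, "
        f"{series.per_vial.min():>12,.2f} EUR at the cheapest year"
    )

print(
    "\nEvery generated profile satisfies the same invariants as the packaged"
    "\nones (sorted approvals, positive doses, cascade fractions in (0,1])."
)
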