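"""Cumulative-per-indication versus non-cumulative indication-based prices.

The cumulative mode reprices the drug after each new approval, pooling all
R&D and all patients so far.  Indication-based pricing (IBP) instead gives
every indication its own price: the first carries the full initial R&D,
later ones only the incremental R&D per new indication over their own
patient pool — so a blockbuster second indication can be priced near the
manufacturing floor while a small late indication stays expensive.
"""

from cbpricer import packaged_population, packaged_profile, price_series

pop = packaged_population()
profile = packaged_profile("daratumumab")

cumulative = price_series(profile, pop, "indication")
ibp = price_series(profile, pop, "ibp")

print(f"{profile.name}: per-vial prices by indication (EUR)")
print(f"{'indication':>10} {'cumulative':>12} {'IBP':>12}")
for k in range(profile.n_indications):
    label = profile.indications[k].label[:48]
    print(
        f"{k + 1:>10} {cumulative.per_vial[k]:>12,.0f} {ibp.per_vial[k]:>12,.0f}   {label}"
    )

assert cumulative.per_vial[0] == ibp.per_vial[0]
print(
    "\nIndication 1 is identical in both modes (one indication, all initial"
    "\nR&D). Later IBP prices reflect only incremental R&D, hence the drop."
)
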