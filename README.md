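# cbpricer

Cost-based pricing of multi-indication drugs.

Expensive oncology drugs such as pembrolizumab and daratumumab accumulate
new approved indications for years after launch. `cbpricer` implements a
cost-based pricing (CBP) model for exactly this situation, for health
economists and HTA analysts: instead of pricing on assessed value, it
builds a price up from what the drug cost to develop and make, amortized
over the patients who can still be treated before the patent expires.

## The model

The price per treatment in evaluation interval *i* is

```
C_tx(i) = ( (C_rd + N_ind * C_ex) / Σ N_p  +  D_ind * C_man ) * (1 + M_p + M_sm)
```

where `C_rd` is the initial R&D cost (capitalized, risk-adjusted), `C_ex`
the incremental R&D cost per new indication, `N_ind` the number of new
indications so far, `Σ N_p` the eligible patients summed over each
indication's remaining patent window, `D_ind` the weighted dose in grams,
`C_man` the manufacturing cost per gram of monoclonal antibody, and `M_p`,
`M_sm` the profit and sales & marketing margins. With a single indication,
a one-year window and `M_sm = 0` this reduces to the classic
single-indication form `(C_rd/N_p + C_man) * (1 + M_p)`.

Eligible patients are projected from incidence rates and a region
population table (UN "more developed regions" aggregate) through a
multiplicative eligibility cascade — cancer subtype, stage, treatment
line, symptomatic disease, clinical eligibility, untreated fraction, trial
participation — and a market share that drops to 50% with one competitor
and 33% with two. Prices are also expressed per vial by allocating the
R&D share per gram of active ingredient and scaling to the vial content.

Three evaluation modes are provided: cumulative per calendar year,
cumulative per indication, and non-cumulative indication-based pricing
(IBP), where each indication carries only its own incremental R&D. A
stepwise deterministic sensitivity analysis (±30% in 10% steps) and a
ten-scenario engine (alternative R&D estimates, manufacturing costs,
margins, patent windows, IBP) complete the analysis surface.

The package ships reconstructed profiles for the two case-study drugs,
calibrated to the published launch-year and cheapest-year per-vial prices
(the original study's per-indication appendix data are not public; see
`docs/methods.md`), plus a seeded synthetic-profile generator.

## Worked example

```python
from cbpricer import (packaged_profile, packaged_population,
                      cumulative_price_by_year, price_series)

pop = packaged_population()
dara = packaged_profile("daratumumab")

b = cumulative_price_by_year(dara, 2015, pop)
print(round(b.per_vial, 2), round(b.rd_per_vial, 2), round(b.total_patients))
# 31941.0 21217.3 7777

print(price_series(dara, pop, "year")[["index", "per_vial"]].round(2).to_string(index=False))
```

```
 index  per_vial
  2015  31941.00
  2016   2175.96
  2017   1576.19
  2018   1001.48
  2019    823.00
  2020    823.00
  2021    842.48
  2022    842.48
  2023    842.48
  2024    842.48
```

At launch (2015) the full initial R&D (€3,795,249,282) is amortized over
the first indication's ~7,800 eligible heavily pretreated multiple-myeloma
patients, giving €21,217 of R&D per 1.8 g vial and a price of €31,941.
Each new indication adds €267,020,244 of R&D but far more patients, so the
price falls to €823 by 2019; the small 2021 indication with only four
patent years left pushes it back up to €842.

The same surface is available from a shell:

```
cbpricer price --drug daratumumab --out dara_prices.csv
cbpricer dsa --drug pembrolizumab --input eligible_patients --out pembro_dsa.csv
cbpricer scenario --drug daratumumab --id 8 --out dara_s8.csv
```

The `examples/` directory contains one narrative script per capability
(price trajectories, indication-based pricing, DSA, scenarios, synthetic
profiles).

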