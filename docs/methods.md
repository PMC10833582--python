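# Methods

## Model

`cbpricer` prices a drug by amortizing development cost over the patients
who can still be treated before patent expiry, then adding manufacturing
cost and margins. Per treatment, in evaluation interval *i*:

```
C_tx(i) = ( (C_rd + N_ind * C_ex) / Σ N_p  +  D_ind * C_man ) * (1 + M_p + M_sm)
```

All money is in euros of the drug's launch year. The model is an
amortization, not a census: patient counts stay real-valued throughout.
Revenue is assumed to stop at patent expiry — no generic-era decay tail is
modelled — and the patent window is shared by all indications of a drug.

### Patient-year aggregation

The single biggest interpretive choice is what `Σ N_p` means at
evaluation year *t*. This package uses: every indication approved in year
`a_j ≤ t` contributes its projected eligible patients for **each**
calendar year from `a_j` through the last patent year. Consequences:

* prices fall as indications accrue (more patient-years join the
  denominator faster than incremental R&D joins the numerator);
* a late-approved indication with a short remaining window adds nearly a
  full R&D block but few patient-years, so prices tick up near expiry —
  the characteristic U-turn of the case-study trajectories;
* within a fixed indication set the yearly price is constant, so the
  yearly series is a step function that moves only when approvals land.

The aggregation is isolated behind a provider interface
(`cbpricer.population.PatientYearProvider`); an alternative reading (e.g.
remaining-window-only amortization) can be swapped in without touching
the pricing code.

### Per-vial prices

R&D per treatment is divided by vials-per-treatment
(`D_ind / vial_grams`); manufacturing is priced per vial directly:

```
C_vial = ( rd_per_treatment / (D_ind / vial_grams) + vial_grams * C_man ) * (1 + M_p + M_sm)
```

When several indications with different doses are active, the per-vial
R&D share uses total grams: `rd_total * vial_grams / Σ (N_p,j * D_j)`,
i.e. R&D is allocated per gram of projected consumption and scaled to the
vial. This is identical to the vials-per-treatment allocation whenever a
drug has one vial size, as both packaged drugs do.

`decompose_per_vial` inverts the composition (strip margins, subtract the
manufacturing floor), raising an error for prices below the
manufacturing floor; compose∘decompose is the identity to 1e-9 relative.

## Parameters

| parameter | meaning | packaged default | unit |
|---|---|---|---|
| `initial_rd` | capitalized, risk-adjusted R&D to first approval | 3,795,249,282 (dara) / 3,165,890,999 (pembro) | EUR |
| `rd_per_new_indication` | incremental R&D per added indication | 267,020,244 / 222,740,834 | EUR |
| `manufacturing_per_gram` | mAb production cost | 42.61 / 35.55 | EUR/g |
| `profit_margin` | margin on total cost | 0.20 | fraction |
| `sales_marketing_margin` | sales & marketing margin | 0.30 | fraction |
| `vial_grams` | active ingredient per vial | 1.8 / 0.1 | g |
| `patent_expiry` | first year without revenue | 2025 / 2028 | year |
| market share | 0/1/2 competitors | 1.0 / 0.5 / 0.33 | fraction |

The 0.33 two-competitor share is the published constant, deliberately not
1/3; both it and the whole step rule are configurable
(`MarketShareRule`). The sales & marketing margin is not printed in the
source study; 0.30 is implied jointly by the base-case and
high-profit-margin launch prices of both drugs
((1+0.765+x)/(1+0.2+x) ratios), and is configurable per profile.

Cost inputs from different publications and base years are converted to
launch-year euros by multiplicative factors (non-tradable-resource
methodology: inflate in the source country, convert at PPP). The factors
are shipped as a fixture derived from published adjusted/unadjusted
pairs, not recomputed from OECD series (which the source study does not
print); `check_factor_consistency` validates the transcription — factors
must be constant within a source (1e-4 relative) and the 2014/2015 ratio
(~0.8342) must be source-independent. The base-case manufacturing cost is
the adjusted €42.61/€35.55 per gram (consistent with all published
sensitivity arithmetic), not the unadjusted ~€55 headline figure.

## Packaged case-study profiles

The original study's per-indication doses and eligibility fractions live
in non-public appendices. The packaged profiles are therefore explicit
**reconstructions**: indication lists, approval years, competitor
schedules, doses and cascade structure are plausible reconstructions of
each drug's approval history, and the per-indication `eligible_share`
values are calibrated so that, against the packaged population table,

* the cumulative launch-year per-vial price equals the published €31,941
  (daratumumab) / €885 (pembrolizumab), and
* the cheapest-year price equals the published €823 / €52,

with a strictly decreasing trajectory in between and a post-minimum
uptick from one small late indication. Everything else printed about the
case studies (cost blocks, patent years, vial contents, incidence rates,
margins) is used as-is. All sensitivity and scenario results are genuine
model arithmetic on top of these calibrated bases, not further
calibration: e.g. the −30%-patients launch price (€45,581) and the
76.5%-margin price (€43,972) are recomputed through the model and agree
with the published values to well under 0.25%.

One documented discrepancy: the source study prints identical DSA ranges
for the profit-margin and manufacturing-cost inputs. The two inputs enter
the price differently (margin rescales the multiplier; manufacturing
moves the pre-margin floor), so identical ranges are arithmetically
implausible; this package computes the manufacturing DSA from first
principles (max ≈ €31,976 for daratumumab rather than the duplicated
€33,219) and treats the printed duplication as a transcription artefact.

The packaged population table is a **synthetic** smooth series of UN-MDR
magnitude (~1.27 billion, shallow peak in the early 2020s); it is not the
UN World Population Prospects output. Because the profiles are calibrated
against this table, all packaged results are self-consistent with it, and
none of the pinned prices depend on its exact shape.

## Sensitivity and scenarios

The DSA varies one input at a time over multiplicative steps (default
0.7…1.3). Varying eligible patients scales every year's projection (the
dose-weighted manufacturing term is unaffected, since it is per patient);
varying the profit margin scales the margin *value* (0.20 → 0.26 at
+30%), not the full multiplier. At step 1.0 the DSA reproduces the base
case bit for bit.

Scenarios 1–6 replace monetary inputs with published alternatives, stored
unadjusted and resolved through the conversion factors for the profile's
launch year (so they are only available for launch years with packaged
factors, 2014/2015, unless factors are supplied). Scenario 3
(uncapitalized R&D) replaces the initial block only by default; an option
scales the per-indication block by the same ratio. Scenario 7 zeroes the
profit margin but keeps sales & marketing (the published text says
"profit margin 0%"; a flag zeroes both). Scenario 8 sets the margin to
0.765. Scenario 9 extends the patent to 2035/2036 for the packaged drugs
(an explicit expiry is required for others). Scenario 10 switches to
indication-based pricing.

## Synthetic generator

`synthetic_profile` emulates the structure of the case studies: staggered
approvals inside an 8–14-year patent window, incidence rates spanning the
published cancer range (2.5–142 per 100k), uniform cascade fractions, a
10% trial fraction, doses of 1–45 g with vial ≤ dose, and 0–2 competitor
entries. Generation is a pure function of the seed. It emulates structure
only — synthetic cascades are not epidemiologically coherent (a drug's
indications are mutually independent draws), so passing tests demonstrate
algorithmic correctness, not real-world price levels.

## Numerical choices

* Full double precision internally; CSV output rounds money to cents
  (optional full precision). Published-price regression tolerances are
  ±0.25% to absorb euro-rounding of the printed bases.
* Evaluation grid is integer calendar years, launch through expiry − 1;
  no sub-year intervals.
* Zero eligible patients raises `UnpriceableError` by default; an
  `allow_unpriceable` flag returns a NaN-priced sentinel record instead.
* Population years missing inside the table are linearly interpolated;
  extrapolation beyond it is off by default (opt-in, linear on the
  nearest five-year trend).
* Profile invariants (sorted indications, first approval = launch,
  approvals before expiry, positive masses, margins in [0,1]) are
  enforced at construction by pydantic; the YAML loader reports every
  violation with its field path.

## Limitations

* The reconstructed cascades reproduce the pinned price anchors but not
  the study's full year-by-year curves or list-price comparisons, whose
  inputs are appendix-bound.
* Prices are ex-factory: no VAT, wholesale or pharmacy margins, no
  packaging/distribution costs.
* No prevalence pool (incident cases only), no country-level
  stratification or differential pricing, no value-based margin linkage,
  no probabilistic sensitivity analysis — the model is deliberately
  deterministic.
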