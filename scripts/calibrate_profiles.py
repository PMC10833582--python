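"""Build the packaged daratumumab / pembrolizumab profile YAMLs.

Reconstruction strategy: cost blocks, patent years, vial contents and
incidence rates are the published case-study inputs. Cascade structure
(stage/line/subtype shares, doses, competitor schedules) is a plausible
reconstruction of each drug's approval history. The per-indication
eligible_share values are the calibrated free parameters:

  * indication 1's share is solved so the launch-year cumulative per-vial
    price equals the published launch price exactly;
  * the last indication approved in the cheapest year has its share solved
    so the minimum yearly price equals the published minimum exactly;
  * intermediate shares are solved against chosen gram targets shaping a
    monotone decline; post-minimum indications keep fixed shares and
    produce the published late-window uptick.
"""
from pathlib import Path

import yaml

from cbpricer.fixtures import fixture_path
from cbpricer.io import load_population
from cbpricer.population import CascadeProvider
from cbpricer.pricing import cumulative_price_by_year, price_series
from cbpricer.types import CostStructure, DrugProfile, EligibilityCascade, IndicationSpec

POP = load_population(fixture_path("population_unmdr.csv"))
PROVIDER = CascadeProvider(POP)

MULT = 1.5  # 1 + 0.2 profit + 0.3 sales & marketing


def rd_per_vial(price, vial, cman):
    return price / MULT - vial * cman


def build(name, launch, expiry, vial, cost, ind_defs, launch_price, min_price, min_year):
    """ind_defs: list of dicts with keys label, year, inc, dose, cascade kwargs
    (without eligible_share), comps, and one of:
      target: grams target -> share solved;  share: fixed share;
      pin: 'launch' | 'min' -> share solved against the price pins."""
    # unit grams per indication at eligible_share = 1
    shares = [None] * len(ind_defs)

    def make_profile(current):
        inds = []
        for d, e in zip(ind_defs, current):
            cascade = EligibilityCascade(eligible_share=e if e is not None else 1.0, **d["cascade"])
            inds.append(
                IndicationSpec(
                    label=d["label"], approval_year=d["year"],
                    incidence_per_100k=d["inc"], grams_per_treatment=d["dose"],
                    cascade=cascade, competitor_schedule=tuple(d.get("comps", ())),
                )
            )
        return DrugProfile(
            name=name, launch_year=launch, patent_expiry=expiry,
            vial_grams=vial, cost=cost, indications=tuple(inds),
        )

    unit = []
    probe = make_profile([1.0] * len(ind_defs))
    for j in range(1, len(ind_defs) + 1):
        _, g = PROVIDER.indication_window(probe, j)
        unit.append(g)

    # launch pin: indication 1 alone
    g_launch = cost.initial_rd * vial / rd_per_vial(launch_price, vial, cost.manufacturing_per_gram)
    shares[0] = g_launch / unit[0]

    # fixed targets / shares
    for i, d in enumerate(ind_defs):
        if "target" in d:
            shares[i] = d["target"] / unit[i]
        elif "share" in d:
            shares[i] = d["share"]

    # min pin: solve the one indication marked pin='min'
    min_idx = next(i for i, d in enumerate(ind_defs) if d.get("pin") == "min")
    active = [i for i, d in enumerate(ind_defs) if d["year"] <= min_year]
    n_new = len(active) - 1
    rd_total = cost.initial_rd + n_new * cost.rd_per_new_indication
    g_min = rd_total * vial / rd_per_vial(min_price, vial, cost.manufacturing_per_gram)
    g_others = sum(shares[i] * unit[i] for i in active if i != min_idx)
    shares[min_idx] = (g_min - g_others) / unit[min_idx]

    for i, (d, e) in enumerate(zip(ind_defs, shares)):
        status = d.get("pin", "target" if "target" in d else "fixed")
        print(f"  ind{i+1} {d['label'][:45]:45s} share={e:.6f} grams={e*unit[i]:,.0f} [{status}]")
        assert 0 < e <= 1, f"infeasible share for indication {i+1}: {e}"

    profile = make_profile(shares)
    series = price_series(profile, POP, "year")
    pv = dict(zip(series["index"], series["per_vial"]))
    print("  per-vial by year:", {y: round(p, 2) for y, p in pv.items()})
    assert abs(pv[launch] - launch_price) < 1e-6 * launch_price
    assert abs(min(pv.values()) - min_price) < 1e-6 * min_price
    assert min(pv, key=pv.get) in (min_year, min_year + 1)
    years = sorted(pv)
    upto = [pv[y] for y in years if y <= min_year]
    assert all(a > b for a, b in zip(upto, upto[1:])), "not strictly decreasing to the minimum"
    assert all(pv[y] >= min_price for y in years)
    return profile, shares


DARA_COST = CostStructure(
    initial_rd=3_795_249_282.0, rd_per_new_indication=267_020_244.0,
    manufacturing_per_gram=42.61, profit_margin=0.2, sales_marketing_margin=0.3,
)

DARA_INDS = [
    dict(label="multiple myeloma, >=3 prior lines, monotherapy", year=2015, inc=7.6, dose=41.4,
         cascade=dict(line_share=0.10, untreated_fraction=0.05, trial_fraction=0.10), pin="launch"),
    dict(label="relapsed multiple myeloma, >=1 prior line, combination", year=2016, inc=7.6, dose=36.0,
         cascade=dict(line_share=0.45, untreated_fraction=0.05, trial_fraction=0.10), target=5.0e6),
    dict(label="relapsed/refractory multiple myeloma, >=2 prior lines, pomalidomide combination",
         year=2017, inc=7.6, dose=36.0,
         cascade=dict(line_share=0.25, untreated_fraction=0.05, trial_fraction=0.10), target=2.678e6),
    dict(label="newly diagnosed multiple myeloma, transplant-ineligible", year=2018, inc=7.6, dose=32.4,
         cascade=dict(line_share=0.55, symptomatic_share=0.9, trial_fraction=0.10), target=6.0e6),
    dict(label="newly diagnosed multiple myeloma, transplant-eligible induction", year=2019, inc=7.6,
         dose=28.8, cascade=dict(line_share=0.40, symptomatic_share=0.9, trial_fraction=0.10), pin="min"),
    dict(label="AL amyloidosis", year=2021, inc=1.2, dose=28.8,
         cascade=dict(stage_share=0.8, trial_fraction=0.10), share=0.39),
]

PEMBRO_COST = CostStructure(
    initial_rd=3_165_890_999.0, rd_per_new_indication=222_740_834.0,
    manufacturing_per_gram=35.55, profit_margin=0.2, sales_marketing_margin=0.3,
)

_P = dict(untreated_fraction=0.25, trial_fraction=0.10)

PEMBRO_INDS = [
    dict(label="unresectable/metastatic melanoma", year=2014, inc=21.7, dose=3.4,
         cascade=dict(stage_share=0.35, **_P), comps=[(2015, 1), (2016, 2)], pin="launch"),
    dict(label="NSCLC, previously treated, PD-L1 positive", year=2015, inc=69.5, dose=3.0,
         cascade=dict(subtype_share=0.7, stage_share=0.60, line_share=0.30, **_P),
         comps=[(2015, 1)], target=1.154e6),
    dict(label="NSCLC, first line, PD-L1 high, monotherapy", year=2016, inc=69.5, dose=5.0,
         cascade=dict(subtype_share=0.30, stage_share=0.65, line_share=0.65, **_P),
         comps=[(2020, 1)], target=2.3e6),
    dict(label="recurrent/metastatic head and neck squamous cell carcinoma", year=2016, inc=21.8,
         dose=4.0, cascade=dict(stage_share=0.60, line_share=0.60, **_P),
         comps=[(2016, 1)], target=1.12e6),
    dict(label="locally advanced/metastatic urothelial carcinoma", year=2017, inc=26.3, dose=3.4,
         cascade=dict(stage_share=0.55, line_share=0.50, **_P), comps=[(2017, 1)], target=0.95e6),
    dict(label="gastric/oesophageal adenocarcinoma, PD-L1 positive", year=2017, inc=32.1, dose=3.2,
         cascade=dict(subtype_share=0.8, stage_share=0.65, line_share=0.50, **_P), target=2.17e6),
    dict(label="melanoma, adjuvant after resection", year=2018, inc=21.7, dose=3.6,
         cascade=dict(stage_share=0.40, **_P), comps=[(2018, 1)], target=1.15e6),
    dict(label="NSCLC, first line, chemotherapy combination", year=2019, inc=69.5, dose=5.0,
         cascade=dict(subtype_share=0.70, stage_share=0.65, line_share=0.70, **_P),
         comps=[(2020, 1)], target=4.3e6),
    dict(label="small cell lung cancer, previously treated", year=2019, inc=69.5, dose=3.0,
         cascade=dict(subtype_share=0.13, stage_share=0.70, line_share=0.60, **_P), target=0.75e6),
    dict(label="renal cell carcinoma, first line combination", year=2019, inc=19.3, dose=5.0,
         cascade=dict(stage_share=0.50, line_share=0.75, **_P), comps=[(2019, 1)], target=1.2e6),
    dict(label="advanced endometrial carcinoma, lenvatinib combination", year=2019, inc=33.7,
         dose=3.0, cascade=dict(stage_share=0.40, line_share=0.60, **_P), pin="min"),
    dict(label="relapsed/refractory classical Hodgkin lymphoma", year=2020, inc=2.5, dose=4.0,
         cascade=dict(stage_share=0.45, line_share=0.40, **_P), comps=[(2020, 1)], share=0.75),
]

HEADER = """\
# Reconstructed drug profile for the {name} case study.
# Cost block, patent window, vial content and incidence rates are published
# inputs (launch-year-adjusted euros). The eligibility cascades are a
# reconstruction: per-indication eligible_share values are calibrated so that
# the cumulative launch-year per-vial price equals EUR {launch_price:,.0f} and the
# cheapest-year per-vial price equals EUR {min_price:,.0f} against the packaged
# population table; all other cascade fractions, doses and competitor
# schedules are plausible choices, not published data.
"""


def emit(profile, path, **hdr):
    doc = profile.model_dump(mode="json")
    text = HEADER.format(**hdr) + yaml.safe_dump(doc, sort_keys=False, width=100)
    Path(path).write_text(text)
    print(f"  wrote {path}")


def main():
    print("daratumumab:")
    dara, _ = build("daratumumab", 2015, 2025, 1.8, DARA_COST, DARA_INDS,
                    launch_price=31941.0, min_price=823.0, min_year=2019)
    emit(dara, fixture_path("daratumumab.yaml"), name="daratumumab",
         launch_price=31941, min_price=823)

    print("pembrolizumab:")
    pembro, _ = build("pembrolizumab", 2014, 2028, 0.1, PEMBRO_COST, PEMBRO_INDS,
                      launch_price=885.0, min_price=52.0, min_year=2019)
    emit(pembro, fixture_path("pembrolizumab.yaml"), name="pembrolizumab",
         launch_price=885, min_price=52)

    # sanity: scenario-8 and DSA anchors
    for prof, launch in ((dara, 2015), (pembro, 2014)):
        b = cumulative_price_by_year(prof, launch, POP)
        print(prof.name, "launch per-vial", round(b.per_vial, 2),
              "scenario8:", round(b.per_vial / 1.5 * 2.065, 2))


if __name__ == "__main__":
    main()
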