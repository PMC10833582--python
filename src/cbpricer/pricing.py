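"""Cost-based price calculations.

A cost-based price (CBP) per treatment amortizes R&D over the eligible
patient population of the remaining patent period and adds manufacturing
cost and margins::

    C_tx = (R&D / N_p + dose_grams * C_man_per_gram) * (1 + M_p + M_sm)

For a single indication and no sales & marketing margin this reduces to
the original single-indication formulation ``(C_rd/N_p + C_man)*(1+M_p)``.
With expanding indications the R&D term accumulates one incremental R&D
block per new indication and the denominator pools each indication's
eligible patients over its own remaining patent window.

Three evaluation modes are provided:

``cumulative_price_by_year``
    indications active at a calendar year; R&D and patients cumulative.
``cumulative_price_by_indication``
    the first *k* indications regardless of calendar year.
``indication_based_price``
    non-cumulative: indication 1 carries the full initial R&D, each later
    indication only its own incremental R&D and its own patient pool.

Per-vial prices allocate the R&D share per gram of active ingredient and
scale it to the vial content, so that drugs with very different dosing can
be compared on the vial prices actually listed.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .errors import DomainError, PatentExpiredError, UnpriceableError
from .population import CascadeProvider, PatientYearProvider, PopulationTable
from .types import DrugProfile, PriceBreakdown, PricingMode

__all__ = [
    "price_per_treatment",
    "per_vial_price",
    "decompose_per_vial",
    "cumulative_price_by_year",
    "cumulative_price_by_indication",
    "indication_based_price",
    "price_series",
]


def price_per_treatment(
    initial_rd: float,
    patients: float,
    manufacturing_per_treatment: float,
    profit_margin: float,
) -> float:
    """Single-indication cost-based price per treatment.

    ``(initial_rd / patients + manufacturing_per_treatment) * (1 + profit_margin)``
    """
    if patients <= 0:
        raise DomainError(f"patients must be > 0, got {patients}")
    return (initial_rd / patients + manufacturing_per_treatment) * (1.0 + profit_margin)


def per_vial_price(
    rd_per_treatment: float,
    manufacturing_per_gram: float,
    grams_per_treatment: float,
    vial_grams: float,
    multiplier: float,
) -> float:
    """Convert a per-treatment R&D share into a per-vial price.

    R&D is allocated per gram of active ingredient and scaled to the vial
    content; manufacturing is priced per vial directly.
    """
    if vial_grams <= 0 or grams_per_treatment <= 0:
        raise DomainError(
            f"masses must be positive (grams_per_treatment={grams_per_treatment}, "
            f"vial_grams={vial_grams})"
        )
    if grams_per_treatment < vial_grams:
        raise DomainError(
            f"grams_per_treatment ({grams_per_treatment}) must be >= vial_grams ({vial_grams})"
        )
    vials_per_treatment = grams_per_treatment / vial_grams
    return (rd_per_treatment / vials_per_treatment + vial_grams * manufacturing_per_gram) * multiplier


def decompose_per_vial(
    per_vial: float,
    vial_grams: float,
    manufacturing_per_gram: float,
    profit_margin: float,
    sales_marketing_margin: float,
) -> tuple[float, float]:
    """Split a per-vial price into pre-margin R&D and manufacturing components.

    Inverse of the per-vial composition: strips the margin multiplier, then
    the per-vial manufacturing cost; the remainder is the R&D share.
    """
    if per_vial <= 0:
        raise DomainError(f"per_vial must be > 0, got {per_vial}")
    multiplier = 1.0 + profit_margin + sales_marketing_margin
    if multiplier <= 0:
        raise DomainError(f"margin multiplier must be > 0, got {multiplier}")
    manuf_component = vial_grams * manufacturing_per_gram
    rd_component = per_vial / multiplier - manuf_component
    if rd_component < 0:
        raise DomainError(
            f"price below manufacturing floor: per_vial={per_vial} implies "
            f"rd_component={rd_component} < 0"
        )
    return rd_component, manuf_component


def _as_provider(pop: PopulationTable | PatientYearProvider) -> PatientYearProvider:
    if isinstance(pop, PopulationTable):
        return CascadeProvider(pop)
    return pop


def _unpriceable(mode: PricingMode, index: int, n: int, multiplier: float) -> PriceBreakdown:
    nan = float("nan")
    return PriceBreakdown(
        mode=mode, index=index, n_indications=n, total_patients=0.0, total_grams=0.0,
        rd_component=nan, manuf_component=nan, rd_per_vial=nan, manuf_per_vial=nan,
        multiplier=multiplier, per_treatment=nan, per_vial=nan, unpriceable=True,
    )


def _breakdown(
    profile: DrugProfile,
    mode: PricingMode,
    index: int,
    rd_total: float,
    indices: Sequence[int],
    provider: PatientYearProvider,
    allow_unpriceable: bool,
) -> PriceBreakdown:
    cost = profile.cost
    multiplier = cost.multiplier
    patients, grams = provider.aggregate(profile, indices)
    if patients <= 0 or grams <= 0:
        if allow_unpriceable:
            return _unpriceable(mode, index, len(indices), multiplier)
        raise UnpriceableError(
            f"{profile.name}: no eligible patients for {mode}={index}; price diverges"
        )
    mean_dose = grams / patients
    rd_component = rd_total / patients
    manuf_component = mean_dose * cost.manufacturing_per_gram
    per_treatment = (rd_component + manuf_component) * multiplier
    rd_per_vial = rd_total * profile.vial_grams / grams
    manuf_per_vial = profile.vial_grams * cost.manufacturing_per_gram
    per_vial = (rd_per_vial + manuf_per_vial) * multiplier
    return PriceBreakdown(
        mode=mode,
        index=index,
        n_indications=len(indices),
        total_patients=patients,
        total_grams=grams,
        rd_component=rd_component,
        manuf_component=manuf_component,
        rd_per_vial=rd_per_vial,
        manuf_per_vial=manuf_per_vial,
        multiplier=multiplier,
        per_treatment=per_treatment,
        per_vial=per_vial,
    )


def cumulative_price_by_year(
    profile: DrugProfile,
    eval_year: int,
    pop: PopulationTable | PatientYearProvider,
    *,
    allow_unpriceable: bool = False,
) -> PriceBreakdown:
    """Cumulative cost-based price at a calendar year within the patent window.

    Total R&D is the initial R&D plus one incremental block per indication
    approved after launch and by ``eval_year``; the denominator pools each
    active indication's eligible patients from its approval through the last
    patent year.
    """
    if eval_year >= profile.patent_expiry:
        raise PatentExpiredError(
            f"{profile.name}: patent expired (eval_year {eval_year} >= expiry {profile.patent_expiry})"
        )
    if eval_year < profile.launch_year:
        raise DomainError(
            f"{profile.name}: eval_year {eval_year} precedes launch {profile.launch_year}"
        )
    indices = [
        j for j, ind in enumerate(profile.indications, start=1) if ind.approval_year <= eval_year
    ]
    n_new = len(indices) - 1
    rd_total = profile.cost.initial_rd + n_new * profile.cost.rd_per_new_indication
    return _breakdown(
        profile, "year", eval_year, rd_total, indices, _as_provider(pop), allow_unpriceable
    )


def cumulative_price_by_indication(
    profile: DrugProfile,
    k: int,
    pop: PopulationTable | PatientYearProvider,
    *,
    allow_unpriceable: bool = False,
) -> PriceBreakdown:
    """Cumulative cost-based price after the first ``k`` indications.

    R&D is the initial block plus ``k - 1`` incremental blocks; patients and
    dosing mass pool indications 1..k, each over its own remaining window.
    """
    if not 1 <= k <= profile.n_indications:
        raise DomainError(
            f"{profile.name}: indication index {k} out of range 1..{profile.n_indications}"
        )
    rd_total = profile.cost.initial_rd + (k - 1) * profile.cost.rd_per_new_indication
    indices = list(range(1, k + 1))
    return _breakdown(
        profile, "indication", k, rd_total, indices, _as_provider(pop), allow_unpriceable
    )


def indication_based_price(
    profile: DrugProfile,
    k: int,
    pop: PopulationTable | PatientYearProvider,
    *,
    allow_unpriceable: bool = False,
) -> PriceBreakdown:
    """Non-cumulative indication-based price for indication ``k``.

    The first indication carries the full initial R&D; every later one only
    the incremental R&D per new indication, amortized over its own patient
    pool from approval to patent expiry.
    """
    if not 1 <= k <= profile.n_indications:
        raise DomainError(
            f"{profile.name}: indication index {k} out of range 1..{profile.n_indications}"
        )
    rd_total = profile.cost.initial_rd if k == 1 else profile.cost.rd_per_new_indication
    return _breakdown(profile, "ibp", k, rd_total, [k], _as_provider(pop), allow_unpriceable)


_MODE_FUNCS = {
    "year": cumulative_price_by_year,
    "indication": cumulative_price_by_indication,
    "ibp": indication_based_price,
}


def price_series(
    profile: DrugProfile,
    pop: PopulationTable | PatientYearProvider,
    mode: PricingMode = "year",
    *,
    allow_unpriceable: bool = False,
) -> pd.DataFrame:
    """Price breakdowns over the full evaluation grid as a tidy DataFrame.

    Mode ``year`` walks calendar years from launch to the last patent year;
    modes ``indication`` and ``ibp`` walk indication numbers 1..n.
    """
    if mode not in _MODE_FUNCS:
        raise DomainError(f"unknown pricing mode {mode!r}; expected year|indication|ibp")
    fn = _MODE_FUNCS[mode]
    if mode == "year":
        grid: Sequence[int] = list(profile.pricing_years())
    else:
        grid = list(range(1, profile.n_indications + 1))
    rows = []
    for index in grid:
        b = fn(profile, index, pop, allow_unpriceable=allow_unpriceable)
        rows.append(
            {
                "drug": profile.name,
                "mode": mode,
                "index": b.index,
                "n_indications": b.n_indications,
                "total_patients": b.total_patients,
                "rd_component": b.rd_component,
                "manuf_component": b.manuf_component,
                "multiplier": b.multiplier,
                "per_treatment": b.per_treatment,
                "per_vial": b.per_vial,
            }
        )
    return pd.DataFrame(rows)
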