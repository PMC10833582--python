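"""Deterministic sensitivity analysis and scenario engine.

The stepwise one-way deterministic sensitivity analysis (DSA) varies one
input at a time over fixed multiplicative steps (default -30%..+30% in 10%
increments) and reprices every evaluation year.  Varying the eligible
patients scales every year's projected population; varying the profit
margin scales the margin value itself (20% -> 26% at +30%), not the whole
multiplier.

The scenario engine replaces single inputs with published alternative
values: R&D confidence bounds and uncapitalized R&D, the 10%-of-initial
rule for per-indication R&D, low/high manufacturing costs, 0% and 76.5%
profit margins, a longer patent window, and indication-based pricing.
Monetary scenario inputs are stored unadjusted (USD) and resolved through
the conversion-factor table for the drug's launch year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .adjustment import packaged_factors
from .errors import DomainError
from .population import CascadeProvider, PopulationTable
from .pricing import price_series
from .types import DrugProfile, PricingMode

__all__ = [
    "DsaSpec",
    "DEFAULT_DSA_STEPS",
    "DSA_INPUTS",
    "dsa_stepwise",
    "dsa_range",
    "ScenarioSpec",
    "build_scenario",
    "run_scenario",
    "run_all_scenarios",
    "SCENARIO_IDS",
]

DEFAULT_DSA_STEPS: tuple[float, ...] = (0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3)

#: DSA-variable inputs: initial R&D, eligible patients, profit margin,
#: manufacturing cost per gram.
DSA_INPUTS = ("initial_rd", "eligible_patients", "profit_margin", "manufacturing_per_gram")


@dataclass(frozen=True)
class DsaSpec:
    """One-way DSA specification: which input to vary and the step multipliers."""

    input_name: str
    steps: tuple[float, ...] = DEFAULT_DSA_STEPS

    def __post_init__(self) -> None:
        if self.input_name not in DSA_INPUTS:
            raise DomainError(
                f"unknown DSA input {self.input_name!r}; expected one of {DSA_INPUTS}"
            )
        if not self.steps:
            raise DomainError("DSA steps must be non-empty")
        if any(s <= 0 for s in self.steps):
            raise DomainError(f"DSA steps must be positive, got {self.steps}")


def _profile_with_cost(profile: DrugProfile, **cost_updates: float) -> DrugProfile:
    return profile.model_copy(update={"cost": profile.cost.model_copy(update=cost_updates)})


def dsa_stepwise(
    profile: DrugProfile,
    spec: DsaSpec,
    pop: PopulationTable,
    *,
    mode: PricingMode = "year",
) -> pd.DataFrame:
    """Reprice every evaluation point at every DSA step.

    Returns a long-format table (drug, input, index, step, per_treatment,
    per_vial).  At step 1.0 every price equals the base case bit for bit.
    """
    base_provider = CascadeProvider(pop)
    frames = []
    for step in spec.steps:
        provider = base_provider
        mod = profile
        if spec.input_name == "eligible_patients":
            provider = base_provider.scaled(step)
        elif spec.input_name == "initial_rd":
            mod = _profile_with_cost(profile, initial_rd=profile.cost.initial_rd * step)
        elif spec.input_name == "profit_margin":
            mod = _profile_with_cost(profile, profit_margin=profile.cost.profit_margin * step)
        elif spec.input_name == "manufacturing_per_gram":
            mod = _profile_with_cost(
                profile, manufacturing_per_gram=profile.cost.manufacturing_per_gram * step
            )
        series = price_series(mod, provider, mode)
        series.insert(1, "input", spec.input_name)
        series.insert(2, "step", step)
        frames.append(series[["drug", "input", "index", "step", "per_treatment", "per_vial"]])
    return pd.concat(frames, ignore_index=True)


def dsa_range(table: pd.DataFrame) -> tuple[float, float]:
    """(min, max) per-vial price over all (index, step) cells of a DSA table."""
    if table is None or len(table) == 0:
        raise DomainError("empty DSA table")
    col = table["per_vial"].dropna()
    if col.empty:
        raise DomainError("DSA table has no priced cells")
    return float(col.min()), float(col.max())


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: resolved input overrides and the pricing mode to use."""

    id: int
    description: str
    cost_overrides: Mapping[str, float] = field(default_factory=dict)
    patent_expiry: int | None = None
    mode: PricingMode = "year"


SCENARIO_IDS = tuple(range(1, 11))

# Unadjusted USD scenario amounts and the cost source whose conversion
# factor adjusts them to launch-year euros. The 10%-of-initial-R&D rule for
# per-indication costs (scenario 4) is resolved through the initial-R&D
# source factor, consistent with the published adjusted value.
_MONEY_SCENARIOS: dict[int, tuple[str, str, float, str]] = {
    1: ("initial_rd", "wouters2020", 3_114_000_000.0, "initial R&D at CI lower bound"),
    2: ("initial_rd", "wouters2020", 6_001_300_000.0, "initial R&D at CI upper bound"),
    3: ("initial_rd", "wouters2020", 1_032_000_000.0, "uncapitalized initial R&D"),
    4: ("rd_per_new_indication", "wouters2020", 446_120_000.0, "per-indication R&D at 10% of initial"),
    5: ("manufacturing_per_gram", "kelly2009_low", 26.0, "low manufacturing cost"),
    6: ("manufacturing_per_gram", "kelly2009_high", 134.0, "high manufacturing cost"),
}

_EXTENDED_PATENT = {"daratumumab": 2035, "pembrolizumab": 2036}


def build_scenario(
    scenario_id: int,
    profile: DrugProfile,
    *,
    factors=None,
    scenario3_applies_to_cex: bool = False,
    scenario7_zero_msm: bool = False,
    scenario9_expiry: int | None = None,
) -> ScenarioSpec:
    """Resolve a scenario id (1..10) against a drug profile.

    ``scenario3_applies_to_cex`` optionally scales per-indication R&D with
    the same uncapitalized/capitalized ratio as the initial block;
    ``scenario7_zero_msm`` additionally zeroes the sales & marketing margin;
    ``scenario9_expiry`` supplies the extended patent year for drugs outside
    the packaged case studies.
    """
    if scenario_id not in SCENARIO_IDS:
        raise DomainError(f"scenario id must be in 1..10, got {scenario_id}")
    if scenario_id in _MONEY_SCENARIOS:
        field_name, source, unadjusted, label = _MONEY_SCENARIOS[scenario_id]
        factors = factors if factors is not None else packaged_factors()
        key = (source, profile.launch_year)
        if key not in factors:
            raise DomainError(
                f"no conversion factor for source {source!r} and launch year "
                f"{profile.launch_year}; supply `factors` explicitly"
            )
        adjusted = unadjusted * factors[key].factor
        overrides = {field_name: adjusted}
        if scenario_id == 3 and scenario3_applies_to_cex:
            ratio = adjusted / profile.cost.initial_rd
            overrides["rd_per_new_indication"] = profile.cost.rd_per_new_indication * ratio
        return ScenarioSpec(scenario_id, label, cost_overrides=overrides)
    if scenario_id == 7:
        overrides = {"profit_margin": 0.0}
        if scenario7_zero_msm:
            overrides["sales_marketing_margin"] = 0.0
        return ScenarioSpec(7, "profit margin 0%", cost_overrides=overrides)
    if scenario_id == 8:
        return ScenarioSpec(8, "profit margin 76.5%", cost_overrides={"profit_margin": 0.765})
    if scenario_id == 9:
        expiry = scenario9_expiry if scenario9_expiry is not None else _EXTENDED_PATENT.get(profile.name)
        if expiry is None:
            raise DomainError(
                f"scenario 9 has no extended patent year for drug {profile.name!r}; "
                "supply `scenario9_expiry`"
            )
        return ScenarioSpec(9, f"patent expiry {expiry}", patent_expiry=expiry)
    return ScenarioSpec(10, "indication-based pricing", mode="ibp")


def apply_scenario(profile: DrugProfile, spec: ScenarioSpec) -> DrugProfile:
    """Profile with the scenario's overrides applied."""
    mod = profile
    if spec.cost_overrides:
        mod = _profile_with_cost(mod, **dict(spec.cost_overrides))
    if spec.patent_expiry is not None:
        mod = mod.model_copy(update={"patent_expiry": spec.patent_expiry})
    return mod


def run_scenario(
    profile: DrugProfile,
    spec: ScenarioSpec | int,
    pop: PopulationTable,
    **build_kwargs,
) -> pd.DataFrame:
    """Price series under one scenario (per year; per indication for IBP)."""
    if isinstance(spec, int):
        spec = build_scenario(spec, profile, **build_kwargs)
    mod = apply_scenario(profile, spec)
    series = price_series(mod, pop, spec.mode)
    series.insert(1, "scenario", spec.id)
    return series


def run_all_scenarios(profile: DrugProfile, pop: PopulationTable, **build_kwargs) -> pd.DataFrame:
    """Concatenated price series for all ten scenarios."""
    frames = [run_scenario(profile, sid, pop, **build_kwargs) for sid in SCENARIO_IDS]
    return pd.concat(frames, ignore_index=True)
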