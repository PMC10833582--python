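"""Synthetic drug profiles and population tables for testing and simulation.

Generated profiles emulate the structure of real multi-indication
oncology drugs: several indications with staggered approval years inside a
patent window, incidence rates in the range of common cancers (a few to
~140 per 100,000), multiplicative eligibility cascades with fractions in
(0, 1], weighted doses in grams, and optional competitor entry.
Generation is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleSpecError
from .population import PopulationTable
from .types import CostStructure, DrugProfile, EligibilityCascade, IndicationSpec

__all__ = ["SyntheticSpec", "synthetic_profile", "synthetic_population", "flat_population"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic-profile generator.

    Defaults mirror the case-study conditions: launch mid-2010s, patent
    windows of 8-14 years, one to two years between indication approvals,
    incidence rates spanning rare lymphomas to breast cancer, and doses of
    a few to ~45 grams per treatment course.
    """

    seed: int
    n_indications: int = 3
    incidence_range: tuple[float, float] = (2.5, 142.0)
    approval_spacing_years: tuple[int, int] = (1, 2)
    patent_window_years: tuple[int, int] = (8, 14)
    dose_range_grams: tuple[float, float] = (1.0, 45.0)
    vial_range_grams: tuple[float, float] = (0.1, 1.8)
    launch_year_range: tuple[int, int] = (2012, 2018)
    initial_rd_range: tuple[float, float] = (1.0e9, 6.0e9)
    rd_per_indication_range: tuple[float, float] = (1.0e8, 5.0e8)
    manufacturing_range: tuple[float, float] = (20.0, 140.0)
    max_competitors: int = 2

    def __post_init__(self) -> None:
        if self.n_indications < 1:
            raise InfeasibleSpecError("n_indications must be >= 1")
        for name in (
            "incidence_range",
            "approval_spacing_years",
            "patent_window_years",
            "dose_range_grams",
            "vial_range_grams",
            "launch_year_range",
            "initial_rd_range",
            "rd_per_indication_range",
            "manufacturing_range",
        ):
            lo, hi = getattr(self, name)
            if not (lo > 0 or name == "launch_year_range") or lo > hi:
                raise InfeasibleSpecError(f"{name} must be a positive ordered range, got ({lo}, {hi})")
        # every indication must be approved strictly before patent expiry
        min_span = self.approval_spacing_years[0] * (self.n_indications - 1)
        if min_span >= self.patent_window_years[1]:
            raise InfeasibleSpecError(
                f"{self.n_indications} indications spaced >= {self.approval_spacing_years[0]} "
                f"years cannot fit a patent window of <= {self.patent_window_years[1]} years"
            )


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def synthetic_profile(spec: SyntheticSpec) -> DrugProfile:
    """Deterministically generate a valid :class:`DrugProfile` from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    launch = int(rng.integers(spec.launch_year_range[0], spec.launch_year_range[1] + 1))

    years = [launch]
    for _ in range(spec.n_indications - 1):
        gap = int(rng.integers(spec.approval_spacing_years[0], spec.approval_spacing_years[1] + 1))
        years.append(years[-1] + gap)
    span = years[-1] - launch
    if span + 1 > spec.patent_window_years[1]:
        raise InfeasibleSpecError(
            f"seed {spec.seed}: approvals {years} do not fit a patent window of "
            f"<= {spec.patent_window_years[1]} years"
        )
    window = int(
        rng.integers(max(spec.patent_window_years[0], span + 1), spec.patent_window_years[1] + 1)
    )
    expiry = launch + window

    vial = _uniform(rng, spec.vial_range_grams)
    indications = []
    for j, year in enumerate(years, start=1):
        dose = float(rng.uniform(max(spec.dose_range_grams[0], vial), spec.dose_range_grams[1]))
        cascade = EligibilityCascade(
            subtype_share=_uniform(rng, (0.3, 1.0)),
            stage_share=_uniform(rng, (0.2, 1.0)),
            line_share=_uniform(rng, (0.2, 1.0)),
            symptomatic_share=_uniform(rng, (0.7, 1.0)),
            eligible_share=_uniform(rng, (0.3, 1.0)),
            untreated_fraction=_uniform(rng, (0.0, 0.25)),
            trial_fraction=0.10,
        )
        n_competitors = int(rng.integers(0, spec.max_competitors + 1))
        schedule = []
        if n_competitors:
            entry_years = sorted(
                int(rng.integers(year, expiry)) for _ in range(n_competitors)
            )
            schedule = [(y, i + 1) for i, y in enumerate(entry_years)]
            # merge same-year entries, keeping the highest count
            schedule = list({y: c for y, c in schedule}.items())
        indications.append(
            IndicationSpec(
                label=f"indication-{j}",
                approval_year=year,
                incidence_per_100k=_uniform(rng, spec.incidence_range),
                grams_per_treatment=dose,
                cascade=cascade,
                competitor_schedule=tuple(schedule),
            )
        )

    cost = CostStructure(
        initial_rd=_uniform(rng, spec.initial_rd_range),
        rd_per_new_indication=_uniform(rng, spec.rd_per_indication_range),
        manufacturing_per_gram=_uniform(rng, spec.manufacturing_range),
        profit_margin=_uniform(rng, (0.1, 0.4)),
        sales_marketing_margin=_uniform(rng, (0.0, 0.4)),
    )
    return DrugProfile(
        name=f"synthetic-{spec.seed}",
        region="synthetic",
        launch_year=launch,
        patent_expiry=expiry,
        vial_grams=vial,
        cost=cost,
        indications=tuple(indications),
    )


def synthetic_population(
    seed: int,
    start_year: int = 2010,
    end_year: int = 2040,
    base_persons: float = 1.27e9,
    annual_drift: float = 5e5,
    noise: float = 2e5,
    region: str = "synthetic",
) -> PopulationTable:
    """Near-stationary population series with mild drift and noise."""
    rng = np.random.default_rng(seed)
    years = range(start_year, end_year + 1)
    entries = {}
    level = base_persons
    for y in years:
        entries[y] = level
        level += annual_drift + rng.normal(0.0, noise)
    return PopulationTable(region=region, entries=entries)


def flat_population(
    persons: float, start_year: int = 2000, end_year: int = 2050, region: str = "flat"
) -> PopulationTable:
    """Constant population table, convenient for closed-form checks."""
    return PopulationTable(region=region, entries={y: persons for y in range(start_year, end_year + 1)})
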