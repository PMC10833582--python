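"""Domain types for cost-based pricing of multi-indication drugs.

The central object is a :class:`DrugProfile`: one drug's cost structure
(initial R&D, incremental R&D per new indication, manufacturing cost per
gram, profit and sales & marketing margins), its patent window, the active
ingredient per vial, and an ordered list of approved indications.  Each
:class:`IndicationSpec` carries the epidemiology needed to project its
eligible patient population: an incidence rate, a multiplicative
eligibility cascade and a competitor schedule that throttles market share.

All money amounts are euros adjusted to the drug's launch year; masses are
grams of active ingredient; rates are incident cases per 100,000 persons
per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DomainError

__all__ = [
    "CostStructure",
    "EligibilityCascade",
    "IndicationSpec",
    "DrugProfile",
    "PriceBreakdown",
    "ConversionFactor",
    "PricingMode",
]

PricingMode = Literal["year", "indication", "ibp"]


class _FrozenModel(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class CostStructure(_FrozenModel):
    """Launch-year-adjusted cost inputs and margins for one drug."""

    initial_rd: float = Field(ge=0, description="Initial R&D cost, EUR (capitalized, risk-adjusted)")
    rd_per_new_indication: float = Field(ge=0, description="Incremental R&D cost per new indication, EUR")
    manufacturing_per_gram: float = Field(ge=0, description="Manufacturing cost per gram of active ingredient, EUR")
    profit_margin: float = Field(ge=0, le=1, description="Profit margin applied on top of cost, fraction")
    sales_marketing_margin: float = Field(ge=0, le=1, description="Sales & marketing margin, fraction")

    @property
    def multiplier(self) -> float:
        """Margin multiplier 1 + profit margin + sales & marketing margin."""
        return 1.0 + self.profit_margin + self.sales_marketing_margin


class EligibilityCascade(_FrozenModel):
    """Multiplicative filters converting incident cases into treated, eligible patients.

    Each share is the fraction surviving that filter; ``untreated_fraction``
    and ``trial_fraction`` are removed (the complement survives).  A filter
    that does not apply to a given indication is left at 1.0 (or 0.0 for the
    two removal fractions).
    """

    subtype_share: float = Field(default=1.0, ge=0, le=1)
    stage_share: float = Field(default=1.0, ge=0, le=1)
    line_share: float = Field(default=1.0, ge=0, le=1)
    symptomatic_share: float = Field(default=1.0, ge=0, le=1)
    eligible_share: float = Field(default=1.0, ge=0, le=1)
    untreated_fraction: float = Field(default=0.0, ge=0, le=1)
    trial_fraction: float = Field(default=0.0, ge=0, le=1)

    @property
    def retention(self) -> float:
        """Overall fraction of incident cases retained (market share excluded)."""
        return (
            self.subtype_share
            * self.stage_share
            * self.line_share
            * self.symptomatic_share
            * self.eligible_share
            * (1.0 - self.untreated_fraction)
            * (1.0 - self.trial_fraction)
        )


class IndicationSpec(_FrozenModel):
    """One approved indication of a drug.

    ``competitor_schedule`` is a step function of calendar year: a list of
    ``(year, competitor_count)`` pairs; the count in force at year *y* is the
    one of the latest entry with year <= *y* (zero before the first entry).
    """

    label: str
    approval_year: int
    incidence_per_100k: float = Field(gt=0)
    grams_per_treatment: float = Field(gt=0, description="Weighted dose per treated patient, grams")
    cascade: EligibilityCascade = Field(default_factory=EligibilityCascade)
    competitor_schedule: tuple[tuple[int, int], ...] = ()

    @model_validator(mode="after")
    def _schedule_sorted(self) -> "IndicationSpec":
        years = [y for y, _ in self.competitor_schedule]
        if years != sorted(years):
            raise ValueError(f"competitor_schedule years must be non-decreasing, got {years}")
        if any(c < 0 for _, c in self.competitor_schedule):
            raise ValueError("competitor counts must be >= 0")
        return self

    def competitors_at(self, year: int) -> int:
        """Number of competitors on the market in ``year``."""
        count = 0
        for entry_year, n in self.competitor_schedule:
            if entry_year <= year:
                count = n
            else:
                break
        return count


class DrugProfile(_FrozenModel):
    """Everything needed to price one drug."""

    schema_version: int = 1
    name: str
    region: str = "UN-MDR"
    launch_year: int
    patent_expiry: int
    vial_grams: float = Field(gt=0, description="Active ingredient per vial, grams")
    cost: CostStructure
    indications: tuple[IndicationSpec, ...] = Field(min_length=1)

    @model_validator(mode="after")
    def _invariants(self) -> "DrugProfile":
        problems: list[str] = []
        if self.patent_expiry <= self.launch_year:
            problems.append(
                f"patent_expiry ({self.patent_expiry}) must be after launch_year ({self.launch_year})"
            )
        years = [ind.approval_year for ind in self.indications]
        if years != sorted(years):
            bad = [
                f"{a}>{b}" for a, b in zip(years, years[1:]) if a > b
            ]
            problems.append(f"indications must be sorted by approval_year (violations: {', '.join(bad)})")
        if self.indications[0].approval_year != self.launch_year:
            problems.append(
                f"first indication approval_year ({self.indications[0].approval_year}) "
                f"must equal launch_year ({self.launch_year})"
            )
        if any(y >= self.patent_expiry for y in years):
            late = [y for y in years if y >= self.patent_expiry]
            problems.append(f"indication approval years {late} fall at or after patent expiry")
        if problems:
            raise ValueError("; ".join(problems))
        return self

    @property
    def n_indications(self) -> int:
        return len(self.indications)

    def pricing_years(self) -> range:
        """Integer evaluation grid: launch year through the last patent year."""
        return range(self.launch_year, self.patent_expiry)


@dataclass(frozen=True)
class PriceBreakdown:
    """Decomposed cost-based price for one evaluation point.

    ``rd_component`` and ``manuf_component`` are pre-margin euro amounts per
    treatment; the per-vial counterparts allocate R&D per gram and scale to
    the vial content.  ``per_treatment`` and ``per_vial`` include margins.
    """

    mode: PricingMode
    index: int                 # calendar year, or indication number (1-based)
    n_indications: int         # indications contributing to this price
    total_patients: float      # sum of eligible patients over remaining patent time
    total_grams: float         # corresponding grams of active ingredient
    rd_component: float        # EUR per treatment, pre-margin
    manuf_component: float     # EUR per treatment, pre-margin
    rd_per_vial: float
    manuf_per_vial: float
    multiplier: float
    per_treatment: float
    per_vial: float
    unpriceable: bool = False

    def __post_init__(self) -> None:
        if self.unpriceable:
            return
        expected = (self.rd_component + self.manuf_component) * self.multiplier
        if not math.isclose(self.per_treatment, expected, rel_tol=1e-9):
            raise DomainError(
                f"inconsistent breakdown: per_treatment={self.per_treatment!r} != "
                f"(rd + manuf) * multiplier = {expected!r}"
            )

    @property
    def grams_per_treatment(self) -> float:
        """Patient-weighted mean dose over the contributing indications."""
        if self.total_patients == 0:
            return float("nan")
        return self.total_grams / self.total_patients


@dataclass(frozen=True)
class ConversionFactor:
    """Multiplicative factor mapping a source-currency amount to launch-year EUR."""

    source_label: str
    source_currency: str
    target_year: int
    factor: float
    note: str = ""

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise DomainError(f"conversion factor must be positive, got {self.factor}")
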