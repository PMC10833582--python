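"""Eligible-patient projection.

Converts a region population table and per-indication incidence rates into
eligible patient counts through the multiplicative eligibility cascade and
a competitor-dependent market share.  Patient counts are real numbers, not
integers: the pricing model amortizes costs over an expected population,
it does not take a census.

The aggregation semantics used by the pricing module live behind the
:class:`CascadeProvider` interface: at evaluation year *t*, every
indication approved in year a_j <= t contributes its projected eligible
patients for every calendar year from a_j through the last patent year.
Alternative readings of the amortization window can be swapped in by
implementing ``aggregate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from .errors import DomainError
from .types import DrugProfile, IndicationSpec

__all__ = [
    "PopulationTable",
    "MarketShareRule",
    "DEFAULT_MARKET_SHARE",
    "market_share",
    "eligible_patients",
    "cumulative_np",
    "CascadeProvider",
    "PatientYearProvider",
]


@dataclass(frozen=True)
class MarketShareRule:
    """Market share as a step function of the number of approved competitors.

    The default reproduces the published rule: full share with no
    competitor, 50% with one, 33% with two or more (the printed value, not
    1/3).
    """

    shares: tuple[float, ...] = (1.0, 0.5, 0.33)

    def __call__(self, competitors_approved: int) -> float:
        if competitors_approved < 0:
            raise DomainError(f"competitors_approved must be >= 0, got {competitors_approved}")
        idx = min(competitors_approved, len(self.shares) - 1)
        return self.shares[idx]


DEFAULT_MARKET_SHARE = MarketShareRule()


def market_share(competitors_approved: int, rule: MarketShareRule = DEFAULT_MARKET_SHARE) -> float:
    """Market share retained given the number of approved competitors."""
    return rule(competitors_approved)


@dataclass(frozen=True)
class PopulationTable:
    """Region population (persons) by calendar year.

    Years missing between table entries are linearly interpolated.
    Extrapolation beyond the table is disabled by default; when enabled it
    is linear on the trend of the five nearest table years.
    """

    region: str
    entries: Mapping[int, float]
    _years: np.ndarray = field(init=False, repr=False, compare=False)
    _persons: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise DomainError("population table is empty")
        years = np.array(sorted(self.entries), dtype=float)
        persons = np.array([self.entries[int(y)] for y in years], dtype=float)
        if np.any(persons <= 0):
            raise DomainError("population table contains non-positive person counts")
        object.__setattr__(self, "_years", years)
        object.__setattr__(self, "_persons", persons)

    @property
    def min_year(self) -> int:
        return int(self._years[0])

    @property
    def max_year(self) -> int:
        return int(self._years[-1])

    def persons(self, year: int | float, extrapolate: bool = False) -> float:
        """Persons alive in ``year``; interpolated, optionally extrapolated."""
        if self.min_year <= year <= self.max_year:
            return float(np.interp(year, self._years, self._persons))
        if not extrapolate:
            raise DomainError(
                f"year {year} outside population table [{self.min_year}, {self.max_year}] "
                "and extrapolation is disabled"
            )
        if year < self.min_year:
            ref_years, ref_persons = self._years[:5], self._persons[:5]
        else:
            ref_years, ref_persons = self._years[-5:], self._persons[-5:]
        slope, intercept = np.polyfit(ref_years, ref_persons, 1)
        value = slope * year + intercept
        return float(max(value, 0.0))


def eligible_patients(
    ind: IndicationSpec,
    year: int,
    pop: PopulationTable,
    *,
    rule: MarketShareRule = DEFAULT_MARKET_SHARE,
    extrapolate: bool = False,
) -> float:
    """Projected eligible patients for one indication in one calendar year.

    persons x incidence/100k, filtered through the eligibility cascade and
    the market share in force that year.
    """
    persons = pop.persons(year, extrapolate=extrapolate)
    incident = persons * ind.incidence_per_100k / 100_000.0
    share = rule(ind.competitors_at(year))
    return incident * ind.cascade.retention * share


def cumulative_np(
    profile: DrugProfile,
    eval_year: int,
    pop: PopulationTable,
    *,
    rule: MarketShareRule = DEFAULT_MARKET_SHARE,
    extrapolate: bool = False,
) -> float:
    """Sum of eligible patients over the remaining patent time at ``eval_year``.

    Each indication approved by ``eval_year`` contributes its projection for
    every year from its approval through the last patent year.
    """
    provider = CascadeProvider(pop, rule=rule, extrapolate=extrapolate)
    indices = [
        j for j, ind in enumerate(profile.indications, start=1) if ind.approval_year <= eval_year
    ]
    patients, _ = provider.aggregate(profile, indices)
    return patients


class PatientYearProvider(Protocol):
    """Supplies aggregated patient counts and dosing mass to the pricing model."""

    def aggregate(
        self, profile: DrugProfile, indication_indices: Sequence[int]
    ) -> tuple[float, float]:
        """Return (total eligible patients, total grams of active ingredient)
        summed over the given indications (1-based indices), each from its
        approval year through the last patent year."""
        ...


@dataclass(frozen=True)
class CascadeProvider:
    """Default patient-year aggregation over the remaining patent window.

    ``patient_scale`` multiplies every projected patient count (and hence
    the dosing mass); the sensitivity module uses it to vary the eligible
    population without touching the cascade definitions.
    """

    pop: PopulationTable
    rule: MarketShareRule = DEFAULT_MARKET_SHARE
    extrapolate: bool = False
    patient_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.patient_scale > 0:
            raise DomainError(f"patient_scale must be positive, got {self.patient_scale}")

    def scaled(self, s: float) -> "CascadeProvider":
        return CascadeProvider(
            self.pop, rule=self.rule, extrapolate=self.extrapolate, patient_scale=self.patient_scale * s
        )

    def indication_window(self, profile: DrugProfile, j: int) -> tuple[float, float]:
        """(patients, grams) for indication ``j`` (1-based) over approval..expiry-1."""
        ind = profile.indications[j - 1]
        patients = 0.0
        for year in range(ind.approval_year, profile.patent_expiry):
            patients += eligible_patients(
                ind, year, self.pop, rule=self.rule, extrapolate=self.extrapolate
            )
        patients *= self.patient_scale
        return patients, patients * ind.grams_per_treatment

    def aggregate(
        self, profile: DrugProfile, indication_indices: Sequence[int]
    ) -> tuple[float, float]:
        total_patients = 0.0
        total_grams = 0.0
        for j in indication_indices:
            if not 1 <= j <= profile.n_indications:
                raise DomainError(
                    f"indication index {j} out of range 1..{profile.n_indications}"
                )
            p, g = self.indication_window(profile, j)
            total_patients += p
            total_grams += g
        return total_patients, total_grams
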