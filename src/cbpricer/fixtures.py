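"""Packaged case-study inputs.

Ships two reconstructed drug profiles (daratumumab and pembrolizumab) and
the region population table they were calibrated against.  The profiles'
cost blocks, patent years, vial contents and incidence rates are the
published case-study inputs; the per-indication eligibility cascades are
reconstructions whose only pinned quantities are the published launch-year
and cheapest-year per-vial prices (the study's appendix with the true
cascades is not public).  See each YAML file's header for the calibration
provenance.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import load_population, load_profile
from .population import PopulationTable
from .types import DrugProfile

__all__ = [
    "packaged_profiles",
    "packaged_profile",
    "packaged_population",
    "fixture_path",
    "PACKAGED_DRUGS",
]

PACKAGED_DRUGS = ("daratumumab", "pembrolizumab")


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("cbpricer.data").joinpath(name)))


def packaged_profile(drug: str) -> DrugProfile:
    """Load one packaged drug profile by name."""
    if drug not in PACKAGED_DRUGS:
        raise KeyError(f"unknown packaged drug {drug!r}; available: {PACKAGED_DRUGS}")
    return load_profile(fixture_path(f"{drug}.yaml"))


def packaged_profiles() -> tuple[DrugProfile, DrugProfile]:
    """The (daratumumab, pembrolizumab) case-study profiles."""
    return packaged_profile("daratumumab"), packaged_profile("pembrolizumab")


def packaged_population() -> PopulationTable:
    """The packaged UN-MDR-style population table (synthetic reconstruction)."""
    return load_population(fixture_path("population_unmdr.csv"))
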