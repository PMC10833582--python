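"""Reading and writing model inputs and results.

Drug profiles are schema-versioned YAML documents; population tables are
CSV with columns region, year, persons.  Money fields are plain numbers
(launch-year euros); currency symbols are never parsed.  Result tables are
written as deterministic CSV: fixed column order, prices rounded to two
decimals unless full precision is requested.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import ValidationError

from .errors import DomainError
from .population import PopulationTable
from .types import DrugProfile

__all__ = [
    "load_profile",
    "dump_profile",
    "load_population",
    "write_price_table",
    "ProfileLoadError",
    "SUPPORTED_SCHEMA_VERSIONS",
]

SUPPORTED_SCHEMA_VERSIONS = (1,)

_PRICE_COLUMNS = [
    "drug",
    "mode",
    "index",
    "rd_component",
    "manuf_component",
    "multiplier",
    "per_treatment",
    "per_vial",
]


class ProfileLoadError(DomainError):
    """A profile document failed validation; message lists every violation."""


def _format_validation_error(path: str, exc: ValidationError) -> str:
    lines = [f"invalid drug profile {path!r}: {exc.error_count()} violation(s)"]
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<document>"
        lines.append(f"  - {loc}: {err['msg']}")
    return "\n".join(lines)


def load_profile(path: str | Path) -> DrugProfile:
    """Load and fully validate a drug-profile YAML document."""
    path = Path(path)
    with path.open() as fh:
        doc: Any = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ProfileLoadError(f"profile {path} is not a mapping document")
    version = doc.get("schema_version")
    if version not in SUPPORTED_SCHEMA_VERSIONS:
        raise ProfileLoadError(
            f"profile {path}: unsupported schema_version {version!r} "
            f"(supported: {SUPPORTED_SCHEMA_VERSIONS})"
        )
    try:
        return DrugProfile.model_validate(doc)
    except ValidationError as exc:
        raise ProfileLoadError(_format_validation_error(str(path), exc)) from exc


def dump_profile(profile: DrugProfile, path: str | Path) -> None:
    """Write a profile as a round-trippable YAML document."""
    doc = profile.model_dump(mode="json")
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_population(path: str | Path) -> PopulationTable:
    """Load a population CSV (columns: region, year, persons; '#' comments)."""
    df = pd.read_csv(path, comment="#")
    missing = {"region", "year", "persons"} - set(df.columns)
    if missing:
        raise DomainError(f"population CSV {path} missing columns {sorted(missing)}")
    regions = df["region"].unique()
    if len(regions) != 1:
        raise DomainError(f"population CSV {path} must contain one region, found {list(regions)}")
    entries = {int(r.year): float(r.persons) for r in df.itertuples(index=False)}
    return PopulationTable(region=str(regions[0]), entries=entries)


def write_price_table(series: pd.DataFrame, path: str | Path, *, full_precision: bool = False) -> None:
    """Write a price series as deterministic CSV.

    Column order is fixed; monetary columns are rounded to cents unless
    ``full_precision`` is set.  Empty input is an error, never an empty file.
    """
    if series is None or len(series) == 0:
        raise DomainError("refusing to write an empty price table")
    extra = [c for c in ("input", "step", "scenario") if c in series.columns]
    columns = _PRICE_COLUMNS[:3] + extra + _PRICE_COLUMNS[3:]
    present = [c for c in columns if c in series.columns]
    out = series[present].copy()
    if not full_precision:
        for col in ("rd_component", "manuf_component", "per_treatment", "per_vial"):
            if col in out.columns:
                out[col] = out[col].round(2)
    out.to_csv(path, index=False)
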