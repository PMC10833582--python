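"""Currency and inflation adjustment of cost inputs.

Cost inputs originate from different publications, currencies and price
years; the model expresses everything in euros of the drug's launch year.
Following the non-tradable-resource methodology (inflate in the source
country, then convert at purchasing-power parity), each (cost source,
target year) pair reduces to a single multiplicative
:class:`~cbpricer.types.ConversionFactor`.  The packaged factor table is
derived from the published adjusted/unadjusted cost-input pairs rather
than recomputed from PPP/CPI series, and a consistency checker validates
the transcribed table: factors must be constant within a source, and the
ratio between the two target years must be source-independent (both years
share one PPP/inflation path).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .errors import DomainError
from .types import ConversionFactor

__all__ = [
    "adjust_cost",
    "derive_factor",
    "check_factor_consistency",
    "ConsistencyReport",
    "packaged_factors",
    "packaged_cost_inputs",
    "REFERENCE_YEAR_RATIO",
]

#: Ratio of the 2014-adjusted to the 2015-adjusted value of the same input;
#: constant across cost sources because both share one PPP/inflation path.
REFERENCE_YEAR_RATIO = 0.8342


def adjust_cost(amount: float, f: ConversionFactor) -> float:
    """Convert ``amount`` (source currency, source year) into launch-year EUR."""
    if amount < 0:
        raise DomainError(f"amount must be >= 0, got {amount}")
    return amount * f.factor


def derive_factor(unadjusted: float, adjusted: float) -> float:
    """Implied conversion factor from an (unadjusted, adjusted) pair."""
    if unadjusted <= 0:
        raise DomainError(f"unadjusted must be > 0, got {unadjusted}")
    return adjusted / unadjusted


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of validating a transcribed cost-input table."""

    table: pd.DataFrame          # per-row implied factors, year ratios, flags
    reference_factor_2015: float
    reference_factor_2014: float
    ok: bool

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[~self.table["consistent"]]


def check_factor_consistency(
    rows: Sequence[tuple[float, float, float]],
    *,
    factor_rel_tol: float = 1e-4,
    year_ratio: float = REFERENCE_YEAR_RATIO,
    year_ratio_tol: float = 1e-3,
) -> ConsistencyReport:
    """Validate (unadjusted, adjusted_2015, adjusted_2014) rows of one cost source.

    A row is flagged when either implied factor deviates more than
    ``factor_rel_tol`` (relative) from the source's reference factor (taken
    from the first row), or its 2014/2015 ratio departs from the
    source-independent reference ratio by more than ``year_ratio_tol``.
    """
    if not rows:
        raise DomainError("no rows supplied")
    ref_2015 = derive_factor(rows[0][0], rows[0][1])
    ref_2014 = derive_factor(rows[0][0], rows[0][2])
    records = []
    for unadjusted, adj_2015, adj_2014 in rows:
        f_2015 = derive_factor(unadjusted, adj_2015)
        f_2014 = derive_factor(unadjusted, adj_2014)
        ratio = adj_2014 / adj_2015
        consistent = (
            abs(f_2015 - ref_2015) <= factor_rel_tol * ref_2015
            and abs(f_2014 - ref_2014) <= factor_rel_tol * ref_2014
            and abs(ratio - year_ratio) <= year_ratio_tol
        )
        records.append(
            {
                "unadjusted": unadjusted,
                "adjusted_2015": adj_2015,
                "adjusted_2014": adj_2014,
                "factor_2015": f_2015,
                "factor_2014": f_2014,
                "year_ratio": ratio,
                "consistent": consistent,
            }
        )
    table = pd.DataFrame(records)
    return ConsistencyReport(
        table=table,
        reference_factor_2015=ref_2015,
        reference_factor_2014=ref_2014,
        ok=bool(table["consistent"].all()),
    )


def _data_path(name: str):
    return resources.files("cbpricer.data").joinpath(name)


def packaged_factors() -> dict[tuple[str, int], ConversionFactor]:
    """Packaged conversion-factor table keyed by (source label, target year)."""
    with _data_path("conversion_factors.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    out: dict[tuple[str, int], ConversionFactor] = {}
    for row in df.itertuples(index=False):
        f = ConversionFactor(
            source_label=row.source_label,
            source_currency=row.source_currency,
            target_year=int(row.target_year),
            factor=float(row.factor),
            note=row.note,
        )
        out[(f.source_label, f.target_year)] = f
    return out


def packaged_cost_inputs() -> pd.DataFrame:
    """Transcribed published cost inputs (unadjusted USD and adjusted EUR)."""
    with _data_path("cost_inputs.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
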