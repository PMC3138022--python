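"""Drinking-water exposure scenario and the permitted-dose table.

Concentrations are always µg/L; permitted doses are always mg/kg/day. The
10⁻³ unit factor lives in exactly one place, :func:`dose_from_concentration`,
so it can never be applied twice.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from ._markers import MISSING_PD, Marker
from .errors import DomainError, ValidationError

__all__ = [
    "ExposureScenario",
    "PermittedDoseRecord",
    "PermittedDoseTable",
    "dose_from_concentration",
    "hazard_quotient",
    "load_permitted_doses",
    "load_default_permitted_doses",
    "resolve_pd",
    "MISSING_PD",
]

logger = logging.getLogger(__name__)

_FIXTURE_NAME = "permitted_doses.csv"


@dataclass(frozen=True)
class ExposureScenario:
    """Generic conservative drinking-water scenario.

    Defaults: 2 L of water per day consumed by a 60 kg adult.
    """

    ingestion_rate_L_day: float = 2.0
    body_weight_kg: float = 60.0

    def __post_init__(self) -> None:
        if self.ingestion_rate_L_day <= 0:
            raise ValidationError("ingestion_rate_L_day must be > 0")
        if self.body_weight_kg <= 0:
            raise ValidationError("body_weight_kg must be > 0")


@dataclass(frozen=True)
class PermittedDoseRecord:
    """One chemical's chronic permitted dose (mg/kg/day) and its source."""

    chemical: str
    pd_mg_kg_day: float
    source_code: int
    molar_basis_note: bool = False

    def __post_init__(self) -> None:
        if self.pd_mg_kg_day <= 0:
            raise ValidationError(
                f"permitted dose for {self.chemical!r} must be > 0, "
                f"got {self.pd_mg_kg_day}"
            )


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


class PermittedDoseTable:
    """Lookup of permitted doses keyed by normalized chemical name.

    Matching is case-insensitive after whitespace normalization; there is no
    fuzzy matching. Absent chemicals resolve to :data:`MISSING_PD` and a
    per-name miss counter is kept so the pipeline can report how often each
    excluded chemical was encountered.
    """

    def __init__(self, records: Iterable[PermittedDoseRecord]) -> None:
        self._records: dict[str, PermittedDoseRecord] = {}
        for rec in records:
            key = _normalize_name(rec.chemical)
            if key in self._records:
                raise ValidationError(f"duplicate chemical in PD table: {rec.chemical!r}")
            self._records[key] = rec
        self.miss_counts: Counter[str] = Counter()

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, chemical: str) -> bool:
        return _normalize_name(chemical) in self._records

    @property
    def records(self) -> tuple[PermittedDoseRecord, ...]:
        return tuple(self._records.values())

    def record(self, chemical: str) -> PermittedDoseRecord | None:
        return self._records.get(_normalize_name(chemical))

    def resolve(self, chemical: str) -> Union[float, Marker]:
        """Permitted dose for ``chemical``, or :data:`MISSING_PD`.

        A missing PD is a handled state — the chemical is excluded from the
        cumulative assessment — not an error.
        """
        rec = self._records.get(_normalize_name(chemical))
        if rec is None:
            self.miss_counts[chemical] += 1
            logger.warning(
                "no permitted dose for %r; excluded from assessment "
                "(occurrence %d)", chemical, self.miss_counts[chemical],
            )
            return MISSING_PD
        return rec.pd_mg_kg_day

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chemical": [r.chemical for r in self.records],
                "pd_mg_kg_day": [r.pd_mg_kg_day for r in self.records],
                "source_code": [r.source_code for r in self.records],
                "molar_basis_note": [r.molar_basis_note for r in self.records],
            }
        )


def dose_from_concentration(conc_ug_L: float, scenario: ExposureScenario | None = None) -> float:
    """Convert a water concentration (µg/L) to a dose (mg/kg/day).

    dose = conc × 10⁻³ (mg/µg) × ingestion rate (L/day) / body weight (kg)
    """
    if scenario is None:
        scenario = ExposureScenario()
    if conc_ug_L < 0:
        raise ValidationError(f"concentration must be >= 0, got {conc_ug_L}")
    return conc_ug_L * 1e-3 * scenario.ingestion_rate_L_day / scenario.body_weight_kg


def hazard_quotient(dose_mg_kg_day: float, pd_mg_kg_day: float) -> float:
    """Ratio of dose to permitted dose (dimensionless)."""
    if pd_mg_kg_day <= 0:
        raise DomainError(f"permitted dose must be > 0, got {pd_mg_kg_day}")
    if dose_mg_kg_day < 0:
        raise ValidationError(f"dose must be >= 0, got {dose_mg_kg_day}")
    return dose_mg_kg_day / pd_mg_kg_day


def load_permitted_doses(
    source: Union[str, Path, pd.DataFrame, Iterable[Mapping[str, object]]],
) -> PermittedDoseTable:
    """Load and validate a permitted-dose table.

    ``source`` may be a CSV path, a DataFrame, or an iterable of mappings;
    required columns are ``chemical``, ``pd_mg_kg_day`` and ``source_code``
    (optional ``molar_basis_note``).
    """
    if isinstance(source, (str, Path)):
        frame = pd.read_csv(source)
    elif isinstance(source, pd.DataFrame):
        frame = source
    else:
        frame = pd.DataFrame(list(source))
    required = {"chemical", "pd_mg_kg_day", "source_code"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"PD table missing columns: {sorted(missing)}")
    records = [
        PermittedDoseRecord(
            chemical=str(row.chemical),
            pd_mg_kg_day=float(row.pd_mg_kg_day),
            source_code=int(row.source_code),
            molar_basis_note=bool(getattr(row, "molar_basis_note", False)),
        )
        for row in frame.itertuples(index=False)
    ]
    return PermittedDoseTable(records)


def load_default_permitted_doses() -> PermittedDoseTable:
    """The packaged chronic-toxicity table (81 chemicals, values verbatim)."""
    with resources.as_file(resources.files("mcrscreen.data") / _FIXTURE_NAME) as path:
        return load_permitted_doses(path)


def resolve_pd(chemical: str, table: PermittedDoseTable) -> Union[float, Marker]:
    """Functional alias for :meth:`PermittedDoseTable.resolve`."""
    return table.resolve(chemical)
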