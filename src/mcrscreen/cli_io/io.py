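"""File formats: monitoring CSVs (long and wide), metrics CSVs, key-value
scenario configs.

Long format follows the USGS remark-code convention: a row's ``remark``
column holding ``<`` marks a non-detect whose ``value_ug_L`` is the
detection limit. Chemicals absent from a sample's rows were not analyzed.
Dates are ISO-8601 only. Floats are written with 12 significant digits so a
write/read round trip is lossless for practical purposes.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .._markers import UNDEFINED, Marker, is_defined
from ..errors import ValidationError
from ..exposure import ExposureScenario
from ..pipeline import (
    AnalyteMeasurement,
    MeasurementStatus,
    NonDetectPolicy,
    SampleMetrics,
    WaterSample,
    classify_by_hi,
)
from ..risk_core import IndividualMetrics

logger = logging.getLogger(__name__)

_FLOAT_FMT = ".12g"
_LONG_COLUMNS = ["sample_id", "site_id", "date", "chemical", "value_ug_L", "remark"]


@dataclass
class RunConfig:
    """Everything one assessment run needs."""

    input_path: str | Path
    out_dir: str | Path
    dialect: str = "long"
    pd_table_path: str | Path | None = None  # None -> packaged fixture
    scenario: ExposureScenario = field(default_factory=ExposureScenario)
    policies: tuple[NonDetectPolicy, ...] = (
        NonDetectPolicy.CASE1_ZERO,
        NonDetectPolicy.CASE2_DL_SQRT2,
    )
    min_detects: int = 5
    hi_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if not self.policies:
            raise ValidationError("at least one non-detect policy is required")
        self.policies = tuple(NonDetectPolicy(p) for p in self.policies)


def _parse_date(raw: object, where: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(raw))
    except ValueError as exc:
        raise ValidationError(f"{where}: date {raw!r} is not ISO-8601") from exc


def _rows_to_samples(frame: pd.DataFrame, errors: list[str]) -> list[WaterSample]:
    samples: list[WaterSample] = []
    for (sample_id, site_id, date_raw), group in frame.groupby(
        ["sample_id", "site_id", "date"], sort=False
    ):
        try:
            date = _parse_date(date_raw, f"sample {sample_id!r}")
            measurements = []
            for row in group.itertuples():
                remark = "" if pd.isna(row.remark) else str(row.remark).strip()
                value = row.value_ug_L
                where = f"line {row.Index + 2}"
                if pd.isna(value):
                    raise ValidationError(
                        f"{where}: missing value_ug_L for {row.chemical!r}"
                    )
                value = float(value)
                if remark == "<":
                    measurements.append(
                        AnalyteMeasurement(
                            chemical=str(row.chemical),
                            status=MeasurementStatus.NONDETECT,
                            detection_limit_ug_L=value,
                        )
                    )
                elif remark == "":
                    measurements.append(
                        AnalyteMeasurement(
                            chemical=str(row.chemical),
                            status=MeasurementStatus.DETECTED,
                            concentration_ug_L=value,
                        )
                    )
                else:
                    raise ValidationError(f"{where}: unknown remark code {remark!r}")
            samples.append(
                WaterSample(
                    sample_id=str(sample_id),
                    site_id=str(site_id),
                    date=date,
                    measurements=tuple(measurements),
                )
            )
        except ValidationError as exc:
            errors.append(str(exc))
    return samples


def read_monitoring_csv(
    path: str | Path, dialect: str = "long"
) -> list[WaterSample]:
    """Read monitoring data; raises with an aggregated report on bad rows."""
    if dialect not in {"long", "wide"}:
        raise ValidationError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    frame = pd.read_csv(path, dtype={"remark": "string"} if dialect == "long" else None)
    if dialect == "wide":
        frame = _wide_to_long(frame)
    missing = set(_LONG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    errors: list[str] = []
    samples = _rows_to_samples(frame, errors)
    if errors:
        report = "\n  ".join(errors)
        raise ValidationError(f"{path}: {len(errors)} invalid record(s):\n  {report}")
    return samples


def _wide_to_long(frame: pd.DataFrame) -> pd.DataFrame:
    id_cols = ["sample_id", "site_id", "date"]
    missing = set(id_cols) - set(frame.columns)
    if missing:
        raise ValidationError(f"wide file missing columns {sorted(missing)}")
    value_cols = [c for c in frame.columns if c.endswith("__value")]
    rows = []
    for _, row in frame.iterrows():
        for vcol in value_cols:
            chem = vcol[: -len("__value")]
            value = row[vcol]
            if pd.isna(value):
                continue  # not analyzed
            remark = row.get(f"{chem}__remark", "")
            remark = "" if pd.isna(remark) else str(remark).strip()
            rows.append(
                {
                    "sample_id": row["sample_id"],
                    "site_id": row["site_id"],
                    "date": row["date"],
                    "chemical": chem,
                    "value_ug_L": value,
                    "remark": remark,
                }
            )
    return pd.DataFrame(rows, columns=_LONG_COLUMNS)


def write_monitoring_csv(samples: Sequence[WaterSample], path: str | Path) -> None:
    """Write samples in the long format (lossless round trip with the reader)."""
    rows = []
    for s in samples:
        for m in s.measurements:
            if m.status is MeasurementStatus.NOT_ANALYZED:
                continue  # absence of a row encodes not-analyzed
            is_nd = m.status is MeasurementStatus.NONDETECT
            value = m.detection_limit_ug_L if is_nd else m.concentration_ug_L
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "site_id": s.site_id,
                    "date": s.date.isoformat(),
                    "chemical": m.chemical,
                    "value_ug_L": format(float(value), _FLOAT_FMT),
                    "remark": "<" if is_nd else "",
                }
            )
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)


def _fmt(value: Union[float, Marker]) -> str:
    return "" if isinstance(value, Marker) else format(float(value), _FLOAT_FMT)


def write_metrics_csv(
    metrics: Sequence[SampleMetrics], path: str | Path, hi_cutoff: float = 1.0
) -> None:
    """One row per sample with its metrics; undefined values are empty cells."""
    rows = []
    for m in metrics:
        rows.append(
            {
                "sample_id": m.sample_id,
                "policy": m.policy.value,
                "hi": _fmt(m.metrics.hi),
                "mhq": _fmt(m.metrics.mhq),
                "mcr": _fmt(m.metrics.mcr),
                "missed_fraction": _fmt(m.metrics.missed_fraction),
                "n_detected": m.n_detected,
                "n_analyzed": m.n_analyzed,
                "n_effective": m.n_effective,
                "top_chemical": m.metrics.top_chemical or "",
                "hi_class": classify_by_hi(m, hi_cutoff),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> list[SampleMetrics]:
    """Read a metrics CSV written by :func:`write_metrics_csv`."""
    frame = pd.read_csv(path, dtype={"sample_id": str, "top_chemical": str})
    out: list[SampleMetrics] = []
    for row in frame.itertuples(index=False):
        def _val(x):
            return UNDEFINED if pd.isna(x) else float(x)

        mcr = _val(row.mcr)
        top = row.top_chemical if isinstance(row.top_chemical, str) else None
        metrics = IndividualMetrics(
            hi=float(row.hi) if not pd.isna(row.hi) else 0.0,
            mhq=float(row.mhq) if not pd.isna(row.mhq) else 0.0,
            mcr=mcr,
            missed_fraction=_val(row.missed_fraction),
            n=int(row.n_effective),
            top_chemical=top,
        )
        out.append(
            SampleMetrics(
                sample_id=str(row.sample_id),
                policy=NonDetectPolicy(row.policy),
                metrics=metrics,
                n_detected=int(row.n_detected),
                n_analyzed=int(row.n_analyzed),
                n_effective=int(row.n_effective),
            )
        )
    return out


def read_scenario_config(path: str | Path) -> ExposureScenario:
    """Parse a ``key = value`` text config into an exposure scenario.

    Recognized keys: ``ingestion_rate_L_day``, ``body_weight_kg``. Lines
    starting with ``#`` and blank lines are ignored; ``:`` also separates.
    """
    values: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sep = "=" if "=" in line else (":" if ":" in line else None)
        if sep is None:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition(sep)
        key = key.strip()
        if key not in {"ingestion_rate_L_day", "body_weight_kg"}:
            raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            values[key] = float(value.strip())
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: bad number {value!r}") from exc
    return ExposureScenario(**values)
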