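"""Dataset-level processing: non-detect policies, sample filtering,
per-sample metrics, HI classification, grouping by n and summary tables.

Two substitution rules are supported for analytes reported below their
detection limit (DL): case 1 sets them to zero, case 2 to DL/√2. Under
case 1 the effective mixture size n is the number of detected chemicals
with a permitted dose; under case 2 it is the number of analyzed chemicals
with a permitted dose.
"""

from __future__ import annotations

import datetime as _dt
import enum
import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd

from ._markers import EXCLUDED, MISSING_PD, UNDEFINED, Marker, is_defined
from .errors import ValidationError
from .exposure import (
    ExposureScenario,
    PermittedDoseTable,
    dose_from_concentration,
    hazard_quotient,
)
from .risk_core import HQVector, IndividualMetrics, MetricValue, individual_metrics

__all__ = [
    "MeasurementStatus",
    "AnalyteMeasurement",
    "WaterSample",
    "NonDetectPolicy",
    "SampleMetrics",
    "GroupSummary",
    "apply_nondetect_policy",
    "filter_samples",
    "compute_sample_metrics",
    "classify_by_hi",
    "group_by_n",
    "summarize_dataset",
]

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


class MeasurementStatus(str, enum.Enum):
    DETECTED = "detected"
    NONDETECT = "nondetect"
    NOT_ANALYZED = "not_analyzed"


class NonDetectPolicy(str, enum.Enum):
    """Substitution rule for non-detects."""

    CASE1_ZERO = "case1_zero"
    CASE2_DL_SQRT2 = "case2_dl_sqrt2"


@dataclass(frozen=True)
class AnalyteMeasurement:
    """One chemical's status in one water sample."""

    chemical: str
    status: MeasurementStatus
    concentration_ug_L: float | None = None
    detection_limit_ug_L: float | None = None

    def __post_init__(self) -> None:
        status = MeasurementStatus(self.status)
        object.__setattr__(self, "status", status)
        if status is MeasurementStatus.DETECTED:
            if self.concentration_ug_L is None:
                raise ValidationError(
                    f"detected measurement for {self.chemical!r} needs a concentration"
                )
            if self.concentration_ug_L < 0:
                raise ValidationError(
                    f"negative concentration for {self.chemical!r}: "
                    f"{self.concentration_ug_L}"
                )
        elif status is MeasurementStatus.NONDETECT:
            if self.detection_limit_ug_L is not None and self.detection_limit_ug_L <= 0:
                raise ValidationError(
                    f"detection limit for {self.chemical!r} must be > 0, "
                    f"got {self.detection_limit_ug_L}"
                )


@dataclass(frozen=True)
class WaterSample:
    """One monitoring sample: an analyte panel with per-chemical results."""

    sample_id: str
    site_id: str
    date: _dt.date
    measurements: tuple[AnalyteMeasurement, ...]

    def __post_init__(self) -> None:
        measurements = tuple(self.measurements)
        object.__setattr__(self, "measurements", measurements)
        if not measurements:
            raise ValidationError(f"sample {self.sample_id!r} has no measurements")
        names = [m.chemical for m in measurements]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(
                f"sample {self.sample_id!r} has duplicate chemicals: {dupes}"
            )

    @property
    def n_detected(self) -> int:
        return sum(m.status is MeasurementStatus.DETECTED for m in self.measurements)

    @property
    def n_analyzed(self) -> int:
        return sum(m.status is not MeasurementStatus.NOT_ANALYZED for m in self.measurements)


@dataclass(frozen=True)
class SampleMetrics:
    """Per-sample risk metrics under one non-detect policy."""

    sample_id: str
    policy: NonDetectPolicy
    metrics: IndividualMetrics
    n_detected: int
    n_analyzed: int
    n_effective: int

    @property
    def defined(self) -> bool:
        return self.metrics.defined


@dataclass(frozen=True)
class GroupSummary:
    """Median HI and MCR for the samples sharing one value of n."""

    n_value: int
    sample_count: int
    median_hi: MetricValue
    median_mcr: MetricValue


def apply_nondetect_policy(
    m: AnalyteMeasurement, policy: NonDetectPolicy
) -> Union[float, Marker]:
    """Effective concentration (µg/L) of one measurement under ``policy``.

    Detected values pass through unchanged; non-detects become 0 (case 1)
    or DL/√2 (case 2); chemicals that were not analyzed are excluded under
    both cases.
    """
    policy = NonDetectPolicy(policy)
    if m.status is MeasurementStatus.NOT_ANALYZED:
        return EXCLUDED
    if m.status is MeasurementStatus.DETECTED:
        return float(m.concentration_ug_L)
    if policy is NonDetectPolicy.CASE1_ZERO:
        return 0.0
    if m.detection_limit_ug_L is None:
        raise ValidationError(
            f"non-detect for {m.chemical!r} has no detection limit; "
            "required under case2_dl_sqrt2"
        )
    return m.detection_limit_ug_L / _SQRT2


def filter_samples(
    samples: Sequence[WaterSample], min_detects: int = 5
) -> list[WaterSample]:
    """Keep samples with at least ``min_detects`` detected chemicals.

    Detects are counted on the raw data, before any permitted-dose lookup,
    so the filter is independent of the non-detect policy. Order preserved.
    """
    if min_detects < 0:
        raise ValidationError("min_detects must be >= 0")
    kept = [s for s in samples if s.n_detected >= min_detects]
    removed = len(samples) - len(kept)
    if removed:
        logger.info(
            "removed %d of %d samples with fewer than %d detects",
            removed, len(samples), min_detects,
        )
    return kept


def compute_sample_metrics(
    sample: WaterSample,
    pd_table: PermittedDoseTable,
    scenario: ExposureScenario | None = None,
    policy: NonDetectPolicy = NonDetectPolicy.CASE1_ZERO,
) -> SampleMetrics:
    """Per-sample HI/MHQ/MCR under one non-detect policy.

    Composes the policy substitution, the dose conversion and the hazard
    quotient, then the individual metrics. Chemicals without a permitted
    dose are excluded (with a warning) and never contribute to n.
    """
    if scenario is None:
        scenario = ExposureScenario()
    policy = NonDetectPolicy(policy)

    entries: list[tuple[str, float]] = []
    for m in sample.measurements:
        # Under case 1, non-detects carry zero concentration and zero HQ;
        # they are left out of the vector so n matches the detect count.
        if policy is NonDetectPolicy.CASE1_ZERO and m.status is MeasurementStatus.NONDETECT:
            continue
        conc = apply_nondetect_policy(m, policy)
        if isinstance(conc, Marker):
            continue
        pd_value = pd_table.resolve(m.chemical)
        if isinstance(pd_value, Marker):
            continue
        dose = dose_from_concentration(conc, scenario)
        entries.append((m.chemical, hazard_quotient(dose, pd_value)))

    if entries:
        try:
            metrics = individual_metrics(HQVector(entries))
        except ValidationError as exc:
            raise ValidationError(f"sample {sample.sample_id!r}: {exc}") from exc
    else:
        logger.warning(
            "sample %r has no usable measurements under %s; metrics undefined",
            sample.sample_id, policy.value,
        )
        metrics = IndividualMetrics.undefined(n=0)

    return SampleMetrics(
        sample_id=sample.sample_id,
        policy=policy,
        metrics=metrics,
        n_detected=sample.n_detected,
        n_analyzed=sample.n_analyzed,
        n_effective=len(entries),
    )


def classify_by_hi(metrics: SampleMetrics | IndividualMetrics, cutoff: float = 1.0) -> str:
    """``"above"`` iff HI strictly exceeds ``cutoff``; HI == cutoff is below."""
    hi = metrics.metrics.hi if isinstance(metrics, SampleMetrics) else metrics.hi
    return "above" if hi > cutoff else "below"


_MIN_GROUP_FOR_MEDIAN = 10


def group_by_n(all_metrics: Sequence[SampleMetrics]) -> list[GroupSummary]:
    """Median HI and MCR for samples grouped by effective n.

    All input metrics must come from a single policy. Records with undefined
    metrics are excluded (and counted); medians are reported only for groups
    of at least 10 samples, otherwise the marker is carried.
    """
    policies = {m.policy for m in all_metrics}
    if len(policies) > 1:
        raise ValidationError(
            f"group_by_n requires metrics from one policy, got {sorted(p.value for p in policies)}"
        )
    defined = [m for m in all_metrics if m.defined]
    dropped = len(all_metrics) - len(defined)
    if dropped:
        logger.info("excluded %d records with undefined metrics from grouping", dropped)

    groups: dict[int, list[SampleMetrics]] = {}
    for m in defined:
        groups.setdefault(m.n_effective, []).append(m)

    summaries = []
    for n_value in sorted(groups):
        members = groups[n_value]
        if len(members) >= _MIN_GROUP_FOR_MEDIAN:
            median_hi: MetricValue = statistics.median(m.metrics.hi for m in members)
            median_mcr: MetricValue = statistics.median(m.metrics.mcr for m in members)
        else:
            median_hi = UNDEFINED
            median_mcr = UNDEFINED
        summaries.append(
            GroupSummary(
                n_value=n_value,
                sample_count=len(members),
                median_hi=median_hi,
                median_mcr=median_mcr,
            )
        )
    return summaries


def _block_stats(metrics: Iterable[SampleMetrics]) -> dict[str, float | int]:
    his = [m.metrics.hi for m in metrics]
    mcrs = [m.metrics.mcr for m in metrics]
    out: dict[str, float | int] = {"n_samples": len(his)}
    if his:
        out.update(
            hi_min=min(his), hi_max=max(his), hi_mean=sum(his) / len(his),
            mcr_min=min(mcrs), mcr_max=max(mcrs), mcr_mean=sum(mcrs) / len(mcrs),
        )
    else:
        out.update(
            hi_min=math.nan, hi_max=math.nan, hi_mean=math.nan,
            mcr_min=math.nan, mcr_max=math.nan, mcr_mean=math.nan,
        )
    return out


def summarize_dataset(
    all_metrics: Sequence[SampleMetrics], hi_cutoff: float = 1.0
) -> pd.DataFrame:
    """Min/max/mean of HI and MCR overall and split by HI class, per policy.

    Undefined records are excluded from the statistics and counted in the
    ``n_undefined`` column. Raises when no record has defined metrics.
    """
    if not all_metrics:
        raise ValidationError("summarize_dataset requires a non-empty metrics list")
    defined = [m for m in all_metrics if m.defined]
    if not defined:
        raise ValidationError("all metric records are undefined; nothing to summarize")

    rows = []
    for policy in sorted({m.policy for m in defined}, key=lambda p: p.value):
        of_policy = [m for m in defined if m.policy is policy]
        n_undefined = sum(
            1 for m in all_metrics if m.policy is policy and not m.defined
        )
        subsets = {
            "all": of_policy,
            f"hi_below_{hi_cutoff:g}": [
                m for m in of_policy if classify_by_hi(m, hi_cutoff) == "below"
            ],
            f"hi_above_{hi_cutoff:g}": [
                m for m in of_policy if classify_by_hi(m, hi_cutoff) == "above"
            ],
        }
        for subset_name, members in subsets.items():
            rows.append(
                {
                    "policy": policy.value,
                    "subset": subset_name,
                    "n_undefined": n_undefined,
                    **_block_stats(members),
                }
            )
    return pd.DataFrame(rows)
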