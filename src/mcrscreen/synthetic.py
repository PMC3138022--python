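"""Synthetic monitoring-data generation.

Emulates the structure of large surface-water pesticide surveys: each sample
is analyzed for a panel of chemicals (panel sizes clustered around two
analytical methods, 48 and 80 analytes), each panel chemical is detected
independently with a per-chemical probability, detected concentrations are
lognormal and non-detects carry the chemical's detection limit. One
designated chemical may be made dominant by multiplying its concentrations.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64);
the seed is a mandatory config field, so generation is reproducible across
runs and platforms.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import ValidationError
from .exposure import ExposureScenario, PermittedDoseTable
from .pipeline import AnalyteMeasurement, MeasurementStatus, WaterSample
from .risk_core import HQVector

__all__ = [
    "SimulationConfig",
    "generate_dataset",
    "fig1_fixture",
    "equitoxic_dataset",
    "default_survey_config",
]

#: Emulation targets: panels cluster at 48 and 80 analytes (mean panel ~70)
#: and an average of ~9 detects per sample.
_DEFAULT_PANEL_SIZES = (48, 80)
_DEFAULT_PANEL_WEIGHTS = (0.3125, 0.6875)  # mean panel size 70
_DEFAULT_DETECT_P = 9.0 / 70.0  # mean detects ~= 9

PerChemical = Union[float, Mapping[str, float]]


def _per_chemical(value: PerChemical, chemical: str, default: float) -> float:
    if isinstance(value, Mapping):
        return float(value.get(chemical, default))
    return float(value)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic survey generator.

    ``detect_probability``, ``log_mean``, ``log_sd`` and ``detection_limits``
    accept either a scalar (applied to every chemical) or a per-chemical
    mapping. ``seed`` has no default: reproducibility is opt-out-proof.
    """

    seed: int
    n_samples: int = 100
    panel_sizes: tuple[int, ...] = _DEFAULT_PANEL_SIZES
    panel_weights: tuple[float, ...] = _DEFAULT_PANEL_WEIGHTS
    detect_probability: PerChemical = _DEFAULT_DETECT_P
    log_mean: PerChemical = math.log(0.05)  # median detected conc 0.05 ug/L
    log_sd: PerChemical = 1.5
    detection_limits: PerChemical = 0.01  # ug/L
    dominant_chemical: str | None = None
    dominance_factor: float = 1.0
    site_id: str = "SYN-SITE"
    start_date: _dt.date = _dt.date(1996, 1, 1)

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValidationError("n_samples must be >= 0")
        if not self.panel_sizes:
            raise ValidationError("panel_sizes must be non-empty")
        if any(p < 1 for p in self.panel_sizes):
            raise ValidationError("panel sizes must be >= 1")
        if len(self.panel_weights) != len(self.panel_sizes):
            raise ValidationError("panel_weights must match panel_sizes in length")
        if any(w < 0 for w in self.panel_weights) or sum(self.panel_weights) <= 0:
            raise ValidationError("panel_weights must be non-negative and sum > 0")
        for name, value in (
            ("detect_probability", self.detect_probability),
        ):
            vals = value.values() if isinstance(value, Mapping) else [value]
            if any(not (0.0 <= float(v) <= 1.0) for v in vals):
                raise ValidationError(f"{name} values must lie in [0, 1]")
        sds = (
            self.log_sd.values() if isinstance(self.log_sd, Mapping) else [self.log_sd]
        )
        if any(float(v) < 0 for v in sds):
            raise ValidationError("log_sd must be >= 0")
        dls = (
            self.detection_limits.values()
            if isinstance(self.detection_limits, Mapping)
            else [self.detection_limits]
        )
        if any(float(v) <= 0 for v in dls):
            raise ValidationError("detection_limits must be > 0")
        if self.dominance_factor < 1.0:
            raise ValidationError("dominance_factor must be >= 1")


def default_survey_config(seed: int, n_samples: int = 100, **overrides) -> SimulationConfig:
    """A config tuned to the survey emulation targets (panels of 48/80,
    ~9 detects per sample on average)."""
    return SimulationConfig(seed=seed, n_samples=n_samples, **overrides)


def generate_dataset(
    config: SimulationConfig, pd_table: PermittedDoseTable
) -> list[WaterSample]:
    """Generate ``config.n_samples`` synthetic water samples.

    Panel chemicals are drawn (without replacement, stable order) from the
    permitted-dose table's chemical list; a panel larger than the table is
    an error. The designated dominant chemical, when present and detected,
    has its concentration multiplied by ``dominance_factor``.
    """
    chemicals = [rec.chemical for rec in pd_table.records]
    if max(config.panel_sizes) > len(chemicals):
        raise ValidationError(
            f"panel size {max(config.panel_sizes)} exceeds the "
            f"{len(chemicals)} chemicals in the PD table"
        )
    if config.dominant_chemical is not None and config.dominant_chemical not in pd_table:
        raise ValidationError(
            f"dominant chemical {config.dominant_chemical!r} is not in the PD table"
        )
    rng = np.random.default_rng(config.seed)
    weights = np.asarray(config.panel_weights, dtype=float)
    weights = weights / weights.sum()

    samples: list[WaterSample] = []
    for i in range(config.n_samples):
        panel_size = int(rng.choice(config.panel_sizes, p=weights))
        panel_idx = rng.choice(len(chemicals), size=panel_size, replace=False)
        panel = [chemicals[j] for j in sorted(panel_idx)]

        measurements = []
        for chem in panel:
            p_detect = _per_chemical(config.detect_probability, chem, _DEFAULT_DETECT_P)
            dl = _per_chemical(config.detection_limits, chem, 0.01)
            if rng.random() < p_detect:
                mu = _per_chemical(config.log_mean, chem, math.log(0.05))
                sd = _per_chemical(config.log_sd, chem, 1.5)
                conc = float(rng.lognormal(mean=mu, sigma=sd))
                if chem == config.dominant_chemical:
                    conc *= config.dominance_factor
                measurements.append(
                    AnalyteMeasurement(
                        chemical=chem,
                        status=MeasurementStatus.DETECTED,
                        concentration_ug_L=conc,
                        detection_limit_ug_L=dl,
                    )
                )
            else:
                measurements.append(
                    AnalyteMeasurement(
                        chemical=chem,
                        status=MeasurementStatus.NONDETECT,
                        detection_limit_ug_L=dl,
                    )
                )
        samples.append(
            WaterSample(
                sample_id=f"SYN{i + 1:05d}",
                site_id=config.site_id,
                date=config.start_date + _dt.timedelta(days=i),
                measurements=tuple(measurements),
            )
        )
    return samples


def fig1_fixture() -> tuple[HQVector, HQVector]:
    """The two illustrative five-chemical HQ vectors.

    Both sum to a Hazard Index of 3; the first is spread across chemicals
    (MCR 3.75), the second dominated by one (MCR ~1.11).
    """
    spread = HQVector(
        [("chemA", 0.6), ("chemB", 0.8), ("chemC", 0.4), ("chemD", 0.5), ("chemE", 0.7)]
    )
    dominated = HQVector(
        [
            ("chemA", 2.7),
            ("chemB", 0.29),
            ("chemC", 0.008),
            ("chemD", 0.001),
            ("chemE", 0.001),
        ]
    )
    return spread, dominated


def equitoxic_dataset(
    n_chemicals: int,
    hq_level: float,
    n_samples: int,
    pd_table: PermittedDoseTable,
    scenario: ExposureScenario | None = None,
    site_id: str = "EQUI-SITE",
) -> list[WaterSample]:
    """Samples in which every chemical contributes exactly ``hq_level`` HQ.

    Concentrations are back-solved through the exposure scenario and each
    chemical's permitted dose, so every sample attains the equitoxic upper
    bound MCR = n exactly.
    """
    if n_chemicals < 1:
        raise ValidationError("n_chemicals must be >= 1")
    if hq_level <= 0:
        raise ValidationError("hq_level must be > 0")
    if scenario is None:
        scenario = ExposureScenario()
    records = pd_table.records[:n_chemicals]
    if len(records) < n_chemicals:
        raise ValidationError(
            f"PD table has only {len(records)} chemicals, need {n_chemicals}"
        )
    measurements = []
    for rec in records:
        # invert dose = conc * 1e-3 * rate / bw and hq = dose / pd
        conc = (
            hq_level
            * rec.pd_mg_kg_day
            * scenario.body_weight_kg
            / scenario.ingestion_rate_L_day
            * 1e3
        )
        measurements.append(
            AnalyteMeasurement(
                chemical=rec.chemical,
                status=MeasurementStatus.DETECTED,
                concentration_ug_L=conc,
            )
        )
    return [
        WaterSample(
            sample_id=f"EQ{i + 1:05d}",
            site_id=site_id,
            date=_dt.date(1996, 1, 1) + _dt.timedelta(days=i),
            measurements=tuple(measurements),
        )
        for i in range(n_samples)
    ]
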