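"""Per-individual mixture-risk metrics.

Given a vector of hazard quotients (HQ, the ratio of a chemical's dose to
its permitted dose) this module computes:

* the Hazard Index (HI) — the sum of HQs, the dose-additive measure of
  cumulative toxicity;
* the Maximum Hazard Quotient (MHQ) — the largest single-chemical HQ;
* the Maximum Cumulative Ratio (MCR) — HI / MHQ, bounded by 1 (one
  chemical carries all the toxicity) and n (an equitoxic mixture of n
  chemicals);
* the missed-toxicity fraction — 1 − 1/MCR, the share of the cumulative
  toxicity that a chemical-by-chemical assessment would not see.

All arithmetic is carried out at full floating precision; rounding happens
only at display time (see :func:`display_round`, half-up to match the
conventional one-decimal reporting of MCR values such as 3.75 → 3.8).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Sequence, Union

from ._markers import UNDEFINED, Marker, is_defined
from .errors import DomainError, ValidationError

__all__ = [
    "HQVector",
    "IndividualMetrics",
    "hazard_index",
    "max_hazard_quotient",
    "mcr",
    "missed_toxicity",
    "individual_metrics",
    "display_round",
    "UNDEFINED",
]

logger = logging.getLogger(__name__)

MetricValue = Union[float, Marker]


@dataclass(frozen=True)
class HQVector:
    """An ordered collection of ``(chemical, hq)`` pairs for one individual.

    Invariants enforced at construction: at least one entry, chemical names
    unique, every HQ finite and non-negative.
    """

    entries: tuple[tuple[str, float], ...]

    def __init__(self, entries: Iterable[tuple[str, float]]) -> None:
        entries = tuple((str(name), float(hq)) for name, hq in entries)
        if not entries:
            raise ValidationError("HQ vector must contain at least one entry")
        seen: set[str] = set()
        for name, hq in entries:
            if name in seen:
                raise ValidationError(f"duplicate chemical in HQ vector: {name!r}")
            seen.add(name)
            if not math.isfinite(hq):
                raise ValidationError(f"non-finite hazard quotient for {name!r}: {hq}")
            if hq < 0:
                raise ValidationError(f"negative hazard quotient for {name!r}: {hq}")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def from_values(cls, hqs: Sequence[float], prefix: str = "chem") -> "HQVector":
        """Build a vector from bare HQ values with synthetic chemical names."""
        width = len(str(len(hqs)))
        return cls((f"{prefix}{i + 1:0{width}d}", hq) for i, hq in enumerate(hqs))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.entries)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(hq for _, hq in self.entries)

    @property
    def chemicals(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)


@dataclass(frozen=True)
class IndividualMetrics:
    """The bundled HI / MHQ / MCR / missed-toxicity result for one individual.

    ``mcr`` and ``missed_fraction`` carry :data:`UNDEFINED` when every HQ is
    zero (the ratio HI/MHQ is then 0/0). The marker propagates; it is never
    coerced to a number.
    """

    hi: float
    mhq: float
    mcr: MetricValue
    missed_fraction: MetricValue
    n: int
    top_chemical: str | None

    def __post_init__(self) -> None:
        if self.hi < 0 or self.mhq < 0:
            raise ValidationError("hi and mhq must be non-negative")
        if is_defined(self.mcr) and not (self.mcr >= 1.0 or math.isclose(self.mcr, 1.0)):
            raise ValidationError(f"mcr must be >= 1, got {self.mcr}")

    @property
    def defined(self) -> bool:
        return is_defined(self.mcr)

    @classmethod
    def undefined(cls, n: int = 0) -> "IndividualMetrics":
        """Metrics for an empty or all-zero HQ vector."""
        return cls(hi=0.0, mhq=0.0, mcr=UNDEFINED, missed_fraction=UNDEFINED,
                   n=n, top_chemical=None)


def hazard_index(hqs: HQVector) -> float:
    """Sum of all hazard quotients (the Hazard Index)."""
    return math.fsum(hqs.values)


def max_hazard_quotient(hqs: HQVector) -> tuple[float, str]:
    """The maximum hazard quotient and the chemical attaining it.

    Ties are broken by taking the alphabetically first tied chemical name;
    the MCR value itself is unaffected by the tie-break.
    """
    best_hq = -math.inf
    best_name = ""
    for name, hq in hqs:
        if hq > best_hq or (hq == best_hq and name < best_name):
            best_hq, best_name = hq, name
    return best_hq, best_name


def mcr(hqs: HQVector) -> MetricValue:
    """Maximum Cumulative Ratio HI/MHQ; :data:`UNDEFINED` when MHQ is zero."""
    hi = hazard_index(hqs)
    mhq, _ = max_hazard_quotient(hqs)
    if mhq == 0.0:
        logger.warning("MCR undefined: all %d hazard quotients are zero", len(hqs))
        return UNDEFINED
    return hi / mhq


def missed_toxicity(mcr_value: float) -> float:
    """Fraction of cumulative toxicity missed by a chemical-by-chemical
    assessment, ``1 - 1/MCR``; lies in [0, 1) for MCR >= 1."""
    if isinstance(mcr_value, Marker):
        raise DomainError("missed_toxicity requires a defined MCR value")
    if mcr_value < 1.0:
        raise DomainError(f"MCR must be >= 1, got {mcr_value}")
    return 1.0 - 1.0 / mcr_value


def individual_metrics(hqs: HQVector) -> IndividualMetrics:
    """Compute HI, MHQ, MCR and missed toxicity for one HQ vector."""
    hi = hazard_index(hqs)
    mhq, top = max_hazard_quotient(hqs)
    if mhq == 0.0:
        logger.warning("metrics undefined: all %d hazard quotients are zero", len(hqs))
        return IndividualMetrics.undefined(n=len(hqs))
    ratio = hi / mhq
    return IndividualMetrics(
        hi=hi,
        mhq=mhq,
        mcr=ratio,
        missed_fraction=1.0 - 1.0 / ratio,
        n=len(hqs),
        top_chemical=top,
    )


def display_round(value: float, ndigits: int = 1) -> float:
    """Round half-up for display (3.75 → 3.8), unlike banker's ``round``."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
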