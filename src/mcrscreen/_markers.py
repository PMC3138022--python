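"""Typed sentinel markers for handled non-value states.

These markers are deliberately not numbers: any arithmetic on them raises,
so an undefined metric can never be silently coerced to 0 or 1.
"""

from __future__ import annotations


class Marker:
    """A named singleton sentinel. Falsy, hashable, arithmetic-proof."""

    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return f"<{self._name}>"

    def __bool__(self) -> bool:
        return False

    def __reduce__(self):
        # pickle round-trips to the module-level singleton
        return (_lookup, (self._name,))


#: Metric cannot be computed (e.g. MCR when every hazard quotient is zero).
UNDEFINED = Marker("UNDEFINED")

#: Measurement contributes nothing under the active non-detect policy.
EXCLUDED = Marker("EXCLUDED")

#: Chemical has no permitted dose and is dropped from the assessment.
MISSING_PD = Marker("MISSING_PD")

_REGISTRY = {m._name: m for m in (UNDEFINED, EXCLUDED, MISSING_PD)}


def _lookup(name: str) -> Marker:
    return _REGISTRY[name]


def is_defined(value: object) -> bool:
    """True when ``value`` is an actual value rather than a marker."""
    return not isinstance(value, Marker)
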