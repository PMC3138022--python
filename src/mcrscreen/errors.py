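"""Exception types raised across the package."""


class MCRScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(MCRScreenError, ValueError):
    """Input data violates a structural or range constraint."""


class DomainError(MCRScreenError, ValueError):
    """A quantity is outside the mathematical domain of an operation."""
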