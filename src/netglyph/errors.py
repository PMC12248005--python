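"""Exception hierarchy and the diagnostic-record type used by the logging contract.

Every user-facing failure raises a subclass of :class:`NetglyphError` carrying a
human-readable message; validation failures additionally carry a structured list
of ``(element_id, message)`` pairs so callers can act on individual offenders.
"""

from __future__ import annotations


class NetglyphError(Exception):
    """Base class for all errors raised by netglyph."""


class ModelParseError(NetglyphError):
    """Raised when the toy reaction-model grammar cannot be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(NetglyphError):
    """Structural validation failure; ``errors`` is a list of (element_id, message)."""

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = list(errors)
        detail = "; ".join(f"{eid}: {msg}" for eid, msg in self.errors)
        super().__init__(f"validation failed: {detail}")


class LayoutError(NetglyphError):
    """Geometry or glyph-bookkeeping failure (unknown glyph, unpositioned glyph...)."""


class StyleError(NetglyphError):
    """Unknown style attribute, template or color name."""


class SBMLReadError(NetglyphError):
    """Input document is not readable as SBML."""
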