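"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`PanelScreenError`,
so callers (notably the CLI) can map failures onto distinct exit codes.
"""

from __future__ import annotations


class PanelScreenError(Exception):
    """Base class for all panelscreen errors."""


class ValidationError(PanelScreenError):
    """Invalid value supplied by the caller (bad allele, empty name, ...)."""


class LookupFailure(PanelScreenError):
    """A named entity (disease term, gene, panel, region label) was not found."""


class DuplicateError(PanelScreenError):
    """Insertion would violate a uniqueness invariant."""


class ParseError(PanelScreenError):
    """Malformed input file; carries a line number when one is known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(ValidationError):
    """JSON document does not conform to the expected schema.

    ``path`` is a JSON-pointer-style location of the offending element.
    """

    def __init__(self, message: str, path: str = "$"):
        self.path = path
        super().__init__(f"{path}: {message}")


class GenerationError(PanelScreenError):
    """Synthetic fixture generation was asked for an infeasible configuration."""
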