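"""Exception hierarchy.

All package-specific failures derive from :class:`MetaboKGError` so callers
can catch a single base class at CLI boundaries.
"""


class MetaboKGError(Exception):
    """Base class for all package errors."""


class ValidationError(MetaboKGError):
    """An entity violates a type invariant (missing key, bad field value)."""


class SchemaError(MetaboKGError):
    """A node label or relationship signature outside the fixed schema."""


class DanglingEndpointError(SchemaError):
    """A relationship references a node that is not in the graph."""


class ParseError(MetaboKGError):
    """A source flat file could not be parsed."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class FormulaError(MetaboKGError):
    """A molecular formula string could not be interpreted."""


class GenericFormulaError(FormulaError):
    """Formula denotes a chemical class or polymer (R-groups, '*', '(...)n'),
    not a specific molecular species."""


class UnknownElementError(FormulaError):
    """Element symbol absent from the isotope mass table."""


class UnmappedNamespaceError(MetaboKGError):
    """A cross-reference namespace token with no identifiers.org mapping."""

    def __init__(self, token: str, context: str = ""):
        ctx = f" (context: {context})" if context else ""
        super().__init__(f"unmapped namespace token {token!r}{ctx}")
        self.token = token


class FixtureSpecError(MetaboKGError):
    """Invalid synthetic-fixture specification."""


class ExportError(MetaboKGError):
    """Bulk export/import failure (missing manifest entry, broken reference)."""
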