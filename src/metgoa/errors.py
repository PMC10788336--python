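"""Exception taxonomy shared across the package.

All domain failures derive from :class:`MetgoaError` so the CLI can map them
to a single exit code, distinct from usage errors and I/O errors.
"""


class MetgoaError(Exception):
    """Base class for data/validation/analysis errors."""


class ParseError(MetgoaError):
    """A source file violates its format; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(MetgoaError):
    """An identifier or record fails its syntactic contract."""


class NotFoundError(MetgoaError):
    """A referenced entity does not exist in the knowledgebase."""


class BuildError(MetgoaError):
    """Knowledgebase assembly produced an unusable result."""


class CycleError(BuildError):
    """The is_a graph is not acyclic; names one term on a cycle."""

    def __init__(self, member: str):
        super().__init__(f"is_a graph contains a cycle through {member}")
        self.member = member


class AnalysisError(MetgoaError):
    """The over-representation analysis cannot proceed on this input."""
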