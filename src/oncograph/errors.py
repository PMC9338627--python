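"""Exception hierarchy shared across the package."""


class OncoGraphError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OncoGraphError):
    """A cohort configuration value is invalid; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class CohortParseError(OncoGraphError):
    """A persisted cohort table is malformed; carries file and line number."""

    def __init__(self, path, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


class AmbiguousLinkError(OncoGraphError):
    """A genetic report matches more than one patient."""

    def __init__(self, report_id: str, candidates):
        self.report_id = report_id
        self.candidates = list(candidates)
        super().__init__(
            f"report {report_id!r} matches multiple patients: "
            + ", ".join(self.candidates)
        )


class ReferentialIntegrityError(OncoGraphError):
    """A relation endpoint is missing from the entity tables."""


class RDFParseError(OncoGraphError):
    """Malformed RDF input; carries a location."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        loc = f"line {line}: " if line is not None else ""
        super().__init__(loc + message)


class QuerySyntaxError(OncoGraphError):
    """Malformed SPARQL query text."""


class UndefinedRuleError(OncoGraphError):
    """An association-rule quantity is undefined (zero-support antecedent
    or empty transaction set)."""
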