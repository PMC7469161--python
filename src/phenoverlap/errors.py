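"""Exception hierarchy shared across the package."""


class PhenoverlapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhenoverlapError):
    """A required column is missing or a file does not match the schema."""


class ValidationError(PhenoverlapError):
    """A record violates a data-model invariant."""


class UndefinedStatisticError(PhenoverlapError):
    """A statistic is undefined for the given input (e.g. zero denominator)."""


class ContractError(PhenoverlapError):
    """A function was called with arguments violating its contract."""


class NoWindowError(PhenoverlapError):
    """No parasitoid occurrence exists in the requested scope."""


class CoverageError(PhenoverlapError):
    """A buffer does not intersect the land-cover grid."""


class GapError(PhenoverlapError):
    """A daily climate series has missing days in the requested interval."""

    def __init__(self, missing_dates):
        self.missing_dates = list(missing_dates)
        preview = ", ".join(str(d) for d in self.missing_dates[:5])
        more = "" if len(self.missing_dates) <= 5 else f" (+{len(self.missing_dates) - 5} more)"
        super().__init__(f"climate series has {len(self.missing_dates)} missing day(s): {preview}{more}")


class AliasingError(PhenoverlapError):
    """The design matrix is rank deficient; names the aliased columns."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__("design matrix is rank deficient; aliased columns: " + ", ".join(self.aliased))


class EmptySelectionError(PhenoverlapError):
    """Filtering produced an empty model frame."""


class ConfigError(PhenoverlapError):
    """A simulation configuration value is invalid."""
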