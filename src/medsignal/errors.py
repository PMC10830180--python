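"""Exception hierarchy.

All package-specific failures derive from :class:`MedsignalError` so the CLI
can map them to a single non-zero exit code while library users can catch
finer-grained classes.
"""


class MedsignalError(Exception):
    """Base class for all medsignal errors."""


class DictionaryFormatError(MedsignalError):
    """Terminology file is structurally malformed (missing columns, bad flags)."""


class DictionaryIntegrityError(MedsignalError):
    """Terminology content violates an invariant (duplicate rows, primary-SOC count)."""


class TermLookupError(MedsignalError, KeyError):
    """A preferred term is absent from the loaded terminology."""


class CaseFormatError(MedsignalError):
    """A case record line could not be parsed or fails schema validation."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class CaseIntegrityError(MedsignalError):
    """A case violates a cross-field invariant (duplicate id, dangling link)."""


class ClassificationError(MedsignalError):
    """A dose could not be classified (e.g. reported term unknown in strict mode)."""


class NonEstimableError(MedsignalError):
    """A disproportionality statistic is undefined for the given counts."""


class ConfigError(MedsignalError):
    """Generator or run configuration is invalid."""
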