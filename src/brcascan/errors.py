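"""Exception hierarchy shared across the package."""


class BrcascanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BrcascanError):
    """Input table or parameter set is structurally unusable (e.g. missing column)."""


class RecordError(BrcascanError):
    """A single input record is invalid; carries the offending line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class HgvsParseError(BrcascanError):
    """An HGVS c. description could not be parsed; carries the offending token."""

    def __init__(self, token: str, message: str = "unparseable HGVS cDNA description"):
        self.token = token
        super().__init__(f"{message}: {token!r}")


class WrongSchemeError(HgvsParseError):
    """A genomic (g.), protein (p.) or other non-cDNA description was supplied."""

    def __init__(self, token: str):
        super().__init__(token, "expected a cDNA (c.) description, got another scheme")


class InfeasibleBinningError(BrcascanError):
    """Requested more bins than there are distinct carrier positions."""


class UndefinedOddsRatioError(BrcascanError):
    """Odds ratio requested on an all-zero contingency table."""


class UndefinedPenetranceError(BrcascanError):
    """Penetrance requested with zero carrier frequency in both arms."""


class UndefinedFractionError(BrcascanError):
    """Recurrence fraction requested with a zero denominator."""


class DomainError(BrcascanError):
    """A numeric argument is outside the function's domain."""
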