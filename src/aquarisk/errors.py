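"""Exception hierarchy shared across the package."""


class AquariskError(Exception):
    """Base class for all package errors."""


class ParseError(AquariskError):
    """A table cell could not be interpreted; names the offending row/column."""


class IntegrityError(AquariskError):
    """Input data violates a structural contract (duplicates, conflicts)."""


class EmptyStratumError(AquariskError):
    """A requested stratum contains no measured values."""


class DomainError(AquariskError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class FeasibilityError(AquariskError):
    """A generator specification cannot be satisfied (e.g. mean outside bounds)."""


class ToxicityTableError(AquariskError, KeyError):
    """A reference dose or slope factor is absent for the requested metal."""


class RouteError(AquariskError):
    """An endpoint was requested for an exposure route it is not defined for."""


class ConfigurationError(AquariskError):
    """A configuration value is missing or invalid."""
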