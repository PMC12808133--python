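"""Exception hierarchy for the dcan package."""


class DcanError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DcanError):
    """A table is missing an expected column or has an unusable header."""


class ParseError(DcanError):
    """A cell could not be parsed as the expected type."""


class ConsistencyError(DcanError):
    """Records contradict each other (e.g. one subject with two ages)."""


class DomainError(DcanError):
    """A value is outside the domain an operation is defined on."""


class ConfigError(DcanError):
    """A configuration object violates its invariants."""


class ContractError(DcanError):
    """A pluggable component broke its interface contract."""


class StateError(DcanError):
    """An object was used before being fitted/initialized."""
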