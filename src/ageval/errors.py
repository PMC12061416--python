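"""Exception hierarchy shared across the package."""


class AgevalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AgevalError):
    """A CSV file is missing mandatory columns or is otherwise malformed."""


class ValidationError(AgevalError):
    """A record violates a domain invariant (the message names the fish)."""


class ConfigError(AgevalError):
    """A simulation or pipeline configuration is inconsistent."""


class UndefinedStatisticError(AgevalError):
    """A statistic is undefined on the given data (e.g. no readable pairs)."""


class ConvergenceError(AgevalError):
    """An iterative fit failed to converge within its iteration budget."""
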