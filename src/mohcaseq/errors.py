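"""Exception hierarchy shared across the package."""


class MohcaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MohcaError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(MohcaError):
    """Input values violate a documented invariant (negative counts, NaN, ...)."""


class DimensionError(MohcaError):
    """Shapes or index conventions disagree (e.g. an entry at i >= j)."""


class ConfigurationError(MohcaError):
    """A configuration value is missing or out of its allowed range."""


class EvaluationError(MohcaError):
    """A model lacks the atoms needed to evaluate a constraint."""
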