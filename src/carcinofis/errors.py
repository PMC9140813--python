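"""Exception hierarchy for carcinofis.

All package-specific failures derive from :class:`CarcinofisError` so callers
(and the CLI) can catch one base class.
"""


class CarcinofisError(Exception):
    """Base class for all carcinofis errors."""


class InvalidInputError(CarcinofisError, ValueError):
    """A crisp input, sample, or record violates a precondition."""


class ConfigurationError(CarcinofisError, ValueError):
    """A system, rule, or config file is internally inconsistent."""


class NoRuleFiredError(CarcinofisError):
    """The aggregate output set is identically zero: no rule covered the input.

    Raised instead of returning a default so a non-diagnosis cannot masquerade
    as a diagnosis.
    """


class GenerationError(CarcinofisError):
    """A synthetic-cohort specification is infeasible (e.g. the parent
    distribution places <1% of its mass inside the truncation bounds)."""


class FormatError(CarcinofisError, ValueError):
    """A patient CSV or config file does not match the documented format."""
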