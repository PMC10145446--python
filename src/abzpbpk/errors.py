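"""Exception and warning types shared across the package."""


class InvalidInputError(ValueError):
    """An input value violates a model precondition (non-finite, negative, ...)."""


class UnderdeterminedError(ValueError):
    """A fit was requested with fewer informative observations than parameters."""


class InsufficientDataError(ValueError):
    """A time-series estimator received too few points to proceed."""


class InconsistentStateError(RuntimeError):
    """A simulation state violates its own invariants (e.g. mass without radius)."""


class ConfigurationError(ValueError):
    """A configuration path or value could not be resolved."""


class UnderdeterminedWarning(UserWarning):
    """A fit proceeded with a reduced parameterization."""
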