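"""Exception hierarchy for the twostep package."""


class TwoStepError(Exception):
    """Base class for all package errors."""


class ConfigError(TwoStepError, ValueError):
    """A configuration object violates one of its invariants."""


class InputError(TwoStepError, ValueError):
    """A function argument is outside its documented domain."""


class DataError(TwoStepError, ValueError):
    """A trial log or covariate table is malformed or incomplete."""


class FittingError(TwoStepError, RuntimeError):
    """All optimization restarts failed to produce a finite optimum."""


class InferenceError(TwoStepError, ValueError):
    """A statistical model cannot be estimated on the given table."""


class DegenerateDesignError(InferenceError):
    """A design column is constant, so its effect is not estimable."""
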