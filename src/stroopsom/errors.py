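"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An estimator or operation parameter is out of its valid range."""


class DataError(ValueError):
    """Input data violates a precondition (shape, range, degeneracy)."""


class ConvergenceError(RuntimeError):
    """A settling process failed to reach its stopping criterion."""
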