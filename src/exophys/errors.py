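"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A simulation or analysis parameter violates its invariant.

    The message names the violated invariant so that configuration errors
    are directly actionable.
    """


class FitError(RuntimeError):
    """A curve fit could not be performed or did not converge."""
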