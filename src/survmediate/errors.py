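"""Exception and warning types shared across the package."""


class InputError(ValueError):
    """Raised when user-supplied inputs violate a documented precondition."""


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a valid result.

    Examples: a constant response after listwise deletion, an empty exposure
    class, complete separation on the point-estimate path, or a bootstrap
    whose surviving-replicate fraction falls below the configured minimum.
    """


class ConvergenceWarning(RuntimeWarning):
    """Emitted when an iterative fit stops without meeting its tolerance."""


class UndefinedProportionWarning(RuntimeWarning):
    """Emitted when the proportion mediated is undefined (total-effect OR = 1)
    or falls outside [0, 1] because direct and indirect effects point in
    opposite directions."""
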