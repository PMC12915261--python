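"""Exception hierarchy for the serialbias package."""


class SerialBiasError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(SerialBiasError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class ShuffleSearchError(SerialBiasError, RuntimeError):
    """The constrained-permutation search exhausted its iteration budget.

    Attributes
    ----------
    best_abs_r1 : float
        Smallest absolute lag-1 autocorrelation encountered before giving up.
    """

    def __init__(self, best_abs_r1: float, max_iter: int):
        self.best_abs_r1 = float(best_abs_r1)
        self.max_iter = int(max_iter)
        super().__init__(
            f"no permutation within tolerance after {max_iter} attempts "
            f"(best |r1| = {self.best_abs_r1:.4g})"
        )


class InsufficientDataError(SerialBiasError, ValueError):
    """Too few usable trials to fit the requested model."""


class CollinearityError(SerialBiasError, ValueError):
    """The regression design matrix is rank deficient.

    Attributes
    ----------
    regressors : tuple of str
        Names of the regressors implicated in the linear dependence.
    """

    def __init__(self, regressors):
        self.regressors = tuple(regressors)
        super().__init__(
            "design matrix is rank deficient; collinear regressors: "
            + ", ".join(self.regressors)
        )


class StudyFailureError(SerialBiasError, RuntimeError):
    """More than the tolerated fraction of simulation replicates failed."""
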