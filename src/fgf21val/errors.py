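"""Exception hierarchy shared across the pipeline.

Input problems (bad values, malformed designs, missing fields) raise
:class:`InputError`; statistics that cannot be computed on the given data
(zero mean, constant vectors, infeasible threshold floors, failed curve
fits) raise dedicated subclasses of :class:`AnalysisError` so callers — and
the CLI exit-code mapping — can tell user error from analytical infeasibility.
"""


class InputError(ValueError):
    """The input violates a documented precondition."""


class MissingDataError(InputError):
    """A required field is absent from a record.

    ``fields`` lists the missing field names.
    """

    def __init__(self, fields):
        self.fields = list(fields)
        super().__init__(f"missing required field(s): {', '.join(self.fields)}")


class AnalysisError(RuntimeError):
    """A statistic could not be computed from otherwise valid input."""


class FitError(AnalysisError):
    """Calibration-curve fitting failed to converge after restarts."""


class UndefinedStatisticError(AnalysisError):
    """The requested statistic is undefined on this data (e.g. CV at mean 0)."""


class InfeasibleError(AnalysisError):
    """No result satisfies the requested constraint (e.g. threshold floors)."""
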