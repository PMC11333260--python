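"""Exception hierarchy.

Exit codes used by the CLI: configuration errors are distinguishable from
data errors and from computation (estimation) errors.
"""


class DrugTargetMRError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(DrugTargetMRError):
    """Invalid configuration: missing columns, unknown profiles, bad paths."""

    exit_code = 2


class DataError(DrugTargetMRError):
    """Input data violates a contract (empty after filtering, mismatched ids...)."""

    exit_code = 3


class SelectionError(DataError):
    """Instrument selection produced an empty set; carries per-step counts."""

    def __init__(self, message, step_counts=None):
        super().__init__(message)
        self.step_counts = dict(step_counts or {})


class EstimationError(DrugTargetMRError):
    """An estimator could not run (degenerate instrument, rank deficiency...)."""

    exit_code = 4


class InsufficientInstrumentsError(EstimationError):
    """Fewer instruments than the estimator's minimum."""


class CollinearityError(EstimationError):
    """Exposure-beta matrix is rank deficient in multivariable MR."""


class StateError(DrugTargetMRError):
    """An operation was applied in an invalid state (e.g. double inversion)."""

    exit_code = 4
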