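"""Exception hierarchy for the gaitmetrics toolkit."""


class GaitMetricsError(Exception):
    """Base class for all toolkit errors."""


class FormatError(GaitMetricsError):
    """A file does not conform to the documented skeleton dialect."""


class DataError(GaitMetricsError):
    """Input data violates a precondition (missing joints, too short, ...)."""


class ParameterError(GaitMetricsError):
    """A supplied parameter is out of its valid range."""


class ValidationError(GaitMetricsError):
    """A produced object violates its invariants (e.g. overlapping segments)."""


class StateError(GaitMetricsError):
    """An operation was invoked on an object in an unusable state."""


class TrainingError(GaitMetricsError):
    """Template fitting failed (e.g. labels without exemplars)."""


class DegenerateSignalError(DataError):
    """A signal is constant or otherwise carries no usable structure."""


class UndefinedFrequencyError(DegenerateSignalError):
    """No dominant spectral peak exists (all-zero / flat spectrum)."""


class UndefinedStatisticError(DataError):
    """A statistic is undefined for the given input (zero variance, all-zero
    differences, fewer events than required)."""
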