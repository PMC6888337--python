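"""Exception hierarchy shared across the pipeline stages."""


class LitsigError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LitsigError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(LitsigError, ValueError):
    """Input data violates a documented precondition (NaN p-values, negative times...)."""


class InvalidLabelsError(LitsigError, ValueError):
    """Group labels do not match what the operation requires."""


class KeyNotFoundError(LitsigError, KeyError):
    """A gene, term, sample or group label is absent; the message names it."""


class FormatError(LitsigError, ValueError):
    """A file does not follow the expected dialect; the message carries a line number."""


class EmptyResultError(LitsigError, ValueError):
    """An intersection or selection came out empty where content is required."""


class InconsistencyError(LitsigError, ValueError):
    """Internal totals disagree (e.g. a marginal exceeds the document total)."""


class DegenerateDataError(LitsigError, ValueError):
    """Data carries no usable signal for the estimator (e.g. all scales zero)."""


class UndefinedTestError(LitsigError, ValueError):
    """The test statistic is undefined for these data (e.g. no events at all)."""
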