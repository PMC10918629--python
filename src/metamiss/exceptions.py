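"""Exception hierarchy for metamiss."""


class MetamissError(Exception):
    """Base class for all metamiss errors."""


class TableParseError(MetamissError, ValueError):
    """A cell in a delimited table could not be parsed as a number."""


class TableValidationError(MetamissError, ValueError):
    """Structural problem with an input table (duplicate ids, empty table, ...)."""


class ConfigError(MetamissError, ValueError):
    """Invalid configuration or hyperparameter value."""


class ImputationError(MetamissError, RuntimeError):
    """An imputation method could not run on the given input."""


class EvaluationError(MetamissError, ValueError):
    """Evaluation (NRMSE) preconditions violated."""


class UnknownMethodError(MetamissError, KeyError):
    """Requested imputation method is not registered."""
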