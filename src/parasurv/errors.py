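"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, data 3, convergence 4).
"""


class ParasurvError(Exception):
    """Base class for all package errors."""


class ConfigError(ParasurvError):
    """Invalid configuration or simulation specification."""


class DataError(ParasurvError):
    """Input data violates a precondition (no events, rank deficiency, ...)."""


class ConvergenceError(ParasurvError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
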