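"""Exception hierarchy for flowflash.

Invalid scalar arguments raise the built-in :class:`ValueError`; the classes
here mark structured failures (bad configuration files, fit breakdowns,
numerical trouble) that callers and the CLI map to distinct exit codes.
"""


class FlowFlashError(Exception):
    """Base class for flowflash-specific failures."""


class ConfigurationError(FlowFlashError):
    """A config file, scheme definition or table is malformed or inconsistent."""


class FitFailureError(FlowFlashError):
    """A fit did not converge or the data cannot support the model.

    ``best_attempt`` carries the best :class:`~flowflash.trace_fitting.FitResult`
    found before giving up, when one exists.
    """

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class AmbiguousComponentError(FlowFlashError):
    """Zero or several fitted components match a requested nominal time constant."""


class DegenerateFitError(FlowFlashError):
    """A calibration fit is underdetermined (e.g. all potentials identical)."""


class NumericalFailureError(FlowFlashError):
    """A linear-algebra or ODE routine failed on a pathological input."""
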