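"""Exception hierarchy for the package."""


class SmartmissError(Exception):
    """Base class for package errors."""


class ParameterError(SmartmissError, ValueError):
    """Invalid simulation or configuration parameter."""


class CalibrationError(SmartmissError, RuntimeError):
    """Intercept calibration failed to bracket or converge."""


class IncompleteDataError(SmartmissError, ValueError):
    """Estimation attempted on data that still contain dropout missingness."""


class SingularDesignError(SmartmissError, ValueError):
    """A treatment cell of the replicated design carries zero weight."""


class EmptyAnalysisError(SmartmissError, ValueError):
    """A missing-data handler produced an empty analysis set."""


class BootstrapDegeneracyError(SmartmissError, RuntimeError):
    """Too many bootstrap resamples produced singular designs."""
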