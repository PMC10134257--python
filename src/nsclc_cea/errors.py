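"""Exception hierarchy for the cost-effectiveness model."""


class NSCLCCEAError(Exception):
    """Base class for all package errors."""


class SchemaError(NSCLCCEAError):
    """A parameter or curve file could not be parsed; names the offending key/line."""


class ParameterValidationError(NSCLCCEAError):
    """A loaded parameter set violates one or more invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("parameter set failed validation:\n" + "\n".join(self.violations))


class UnknownParameterError(NSCLCCEAError):
    """A dotted parameter path does not address any scalar in the parameter set."""


class StrategyUnavailableError(NSCLCCEAError):
    """The strategy has no hazard ratios for the requested PD-L1 stratum."""


class CalibrationError(NSCLCCEAError):
    """Survival calibration failed (e.g. too-short follow-up, excessive clipping)."""


class NonMonotoneError(NSCLCCEAError):
    """A response assumed monotone (for threshold search) was found not to be."""


class ThresholdNotFoundError(NSCLCCEAError):
    """No parameter value within the search interval attains the target ICER."""


class UndefinedICERError(NSCLCCEAError):
    """ICER requested between two strategies with equal effects."""
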