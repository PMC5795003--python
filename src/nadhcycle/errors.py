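"""Exception hierarchy shared across the pipeline.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class NadhcycleError(Exception):
    """Base class for all package errors."""


class ConfigError(NadhcycleError):
    """Invalid configuration (bad parameter values, infeasible setup)."""


class DataError(NadhcycleError):
    """Input data violates a precondition (shapes, ranges, missing signal)."""


class CalibrationError(ConfigError):
    """A calibration target cannot be met within the search bracket."""
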