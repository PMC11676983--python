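"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError (and its
CalibrationError subclass) -> 3, a non-converged fit -> 4.
"""


class TMSDRError(Exception):
    """Base class for all package errors."""


class ConfigError(TMSDRError):
    """Invalid or incomplete configuration (missing key, bad value)."""


class DataError(TMSDRError):
    """Input trace data is missing, malformed, or inconsistent."""


class CalibrationError(DataError):
    """Calibration levels are unusable (positive control <= baseline)."""


class SimulationError(TMSDRError):
    """ODE integration failed; carries the solver diagnostics."""
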