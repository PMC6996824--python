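"""Exception types shared across the package."""


class SparktonoError(Exception):
    """Base class for all package errors."""


class ParameterError(SparktonoError, ValueError):
    """A physical or numerical parameter is out of its valid range."""


class ConfigurationError(SparktonoError, ValueError):
    """A configuration is internally inconsistent (e.g. packet outside trace)."""


class ExtractionError(SparktonoError, RuntimeError):
    """A time-of-flight extraction step cannot produce an estimate."""


class FitError(SparktonoError, RuntimeError):
    """A calibration fit is degenerate or failed to converge."""


class ProtocolError(SparktonoError, RuntimeError):
    """A teaching/validation protocol rule was violated."""


class FormatError(SparktonoError, ValueError):
    """An input file does not satisfy the format contract."""
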