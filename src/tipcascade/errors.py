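"""Exception hierarchy shared across the package."""


class TipcascadeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TipcascadeError, ValueError):
    """A model or simulation parameter is outside its admissible range."""


class PartitionError(ParameterError):
    """Population group sizes violate 0 <= A <= P <= N."""


class InvalidDistributionError(TipcascadeError, ValueError):
    """A threshold CDF is non-monotone or leaves the unit interval."""


class UndefinedCurveError(TipcascadeError, ValueError):
    """An empirical threshold curve is undefined (no contingent individuals)."""


class NoFullCascadeError(TipcascadeError, RuntimeError):
    """No standard deviation in the scanned range produces a full cascade."""


class CuspNotFoundError(TipcascadeError, RuntimeError):
    """No bistable window exists anywhere in the scanned parameter grid."""


class ConfigError(TipcascadeError, ValueError):
    """An experiment configuration file is malformed or inconsistent."""
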