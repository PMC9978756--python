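"""Error taxonomy: configuration, data, and numeric failures."""


class FracvalError(Exception):
    """Base class for all package errors."""


class ConfigError(FracvalError):
    """Invalid configuration (hazard config, run config, equation schema)."""


class DataError(FracvalError):
    """Malformed or inconsistent input data."""


class NumericError(FracvalError):
    """Numerical failure (non-convergence, degenerate input)."""
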