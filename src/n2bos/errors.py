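"""Exception hierarchy."""


class N2BosError(Exception):
    """Base class for all package errors."""


class ConfigurationError(N2BosError):
    """Invalid configuration: non-physical parameters, bad proportions, missing references."""


class AnalysisError(N2BosError):
    """A computation cannot proceed on the given data (degenerate window, empty pool)."""


class ValidationError(N2BosError):
    """Malformed input data (schema violations, duplicate rows)."""
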