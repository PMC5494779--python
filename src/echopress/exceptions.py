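"""Exception hierarchy for the echopress pipeline.

Stage errors derive from :class:`EchopressError` so the CLI can map them to
exit codes (config errors -> 2, stage errors -> 3).
"""


class EchopressError(Exception):
    """Base class for all echopress errors."""


class ConfigError(EchopressError):
    """Invalid or unparsable configuration."""


class ConfigurationError(EchopressError):
    """Physically inconsistent simulation setup (e.g. unresolvable echoes)."""


class CalibrationError(EchopressError):
    """Endpoint calibration has no solution in the admissible interval."""


class DetectionError(EchopressError):
    """Fewer resolvable echoes than required were found."""


class FitError(EchopressError):
    """Parabolic peak fit is ill-posed (edge maximum, too few points)."""


class InversionError(EchopressError):
    """Amplitude implies a reflection coefficient outside (-1, 1)."""


class AggregationError(EchopressError):
    """Empty group or inconsistent table during aggregation."""


class AnalysisError(EchopressError):
    """Invalid input to a statistical routine."""
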