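"""Exception hierarchy."""


class BoneScrewError(Exception):
    """Base class for all package errors."""


class GeometryError(BoneScrewError, ValueError):
    """Invalid screw/hole geometry or coefficient derivation request."""


class ConfigError(BoneScrewError, ValueError):
    """Malformed configuration or input file."""


class SignalError(BoneScrewError, ValueError):
    """Invalid trace or filter parameters."""


class NoMotionError(SignalError):
    """Recording start rule found no rotation past the threshold."""


class NoTighteningError(SignalError):
    """Tightening-onset detector found no derivative threshold crossing."""


class EstimationError(BoneScrewError, ValueError):
    """Strength identification cannot be performed on the given segment."""


class AnalysisError(BoneScrewError, ValueError):
    """Degenerate input to a statistical summary."""
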