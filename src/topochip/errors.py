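"""Exception hierarchy."""


class TopoChipError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TopoChipError, ValueError):
    """Invalid parameter combination (resolutions, ranges, probabilities)."""


class LayoutError(TopoChipError, ValueError):
    """Chip-layout arithmetic does not add up."""


class CalibrationError(TopoChipError, ValueError):
    """Control-based threshold calibration cannot proceed."""


class SchemaError(TopoChipError, ValueError):
    """A file does not conform to the expected tabular schema."""
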