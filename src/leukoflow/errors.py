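"""Exception hierarchy shared across the package."""


class LeukoflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LeukoflowError):
    """Malformed FCS file: inconsistent header/TEXT/DATA segments or non-finite data."""


class PanelMismatch(LeukoflowError):
    """A required ALOT panel channel could not be mapped, or channel count is wrong."""


class UnknownLabel(LeukoflowError):
    """A cell-type or diagnosis label outside the fixed vocabulary."""


class CapExceeded(LeukoflowError):
    """Event count above the configured per-sample hard cap."""


class AlignmentError(LeukoflowError):
    """Per-event vectors (labels, predictions) not aligned to the event matrix."""


class ConfigError(LeukoflowError):
    """Invalid model or pipeline configuration."""


class DegenerateTraining(LeukoflowError):
    """Training input cannot support learning (e.g. a single class present)."""


class DegenerateCounts(LeukoflowError):
    """Confusion counts that are all zero."""


class StratificationError(LeukoflowError):
    """A diagnosis stratum too small for the requested stratified split."""


class LeakageError(LeukoflowError):
    """Overlap between training and test sample ids."""


class DependencyError(LeukoflowError):
    """A required upstream checkpoint or artifact is missing."""
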