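"""Exception hierarchy for the ultrametric pipeline."""


class UltrametricError(Exception):
    """Base class for all pipeline errors."""


class InputFormatError(UltrametricError):
    """Raised when an image or table does not meet the declared format."""


class SchemaError(UltrametricError):
    """Raised when a CSV is missing mandatory columns or has invalid rows."""


class EmptyDistributionError(UltrametricError):
    """Raised when a size-frequency distribution is requested for no data."""


class InsufficientDataError(UltrametricError):
    """Raised when an operation needs more observations than supplied."""


class NoCountableOocytesError(UltrametricError):
    """Raised when a fish has no oocytes in either OR counting window."""


class CalibrationUnavailableError(UltrametricError):
    """Raised when packing-density calibration is required but not supplied."""


class InconsistentCountsError(UltrametricError):
    """Raised when stereological counts contradict each other."""


class BiometryError(UltrametricError):
    """Raised on physically impossible biometry (e.g. ovary heavier than fish)."""


class DegenerateDataError(UltrametricError):
    """Raised when a statistical test is undefined for the given data."""
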