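"""Exception hierarchy shared across the package."""


class RitualSyncError(Exception):
    """Base class for all package-specific errors."""


class SizingError(RitualSyncError):
    """An input is too short / too small for the requested operation."""


class UnprocessableSeriesError(RitualSyncError):
    """A series cannot be processed at all (e.g. every sample missing)."""


class DegenerateSeriesError(RitualSyncError):
    """A series is degenerate for the operation (e.g. constant, so no z-score)."""


class CalibrationError(RitualSyncError):
    """Radius calibration could not reach the requested recurrence band."""


class DataIntegrityError(RitualSyncError):
    """Input tables violate a structural contract (e.g. asymmetric distances)."""


class ConfigurationError(RitualSyncError):
    """A configuration is internally inconsistent (e.g. two imams)."""
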