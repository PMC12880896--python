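"""Exception hierarchy for the gymlanding pipeline."""


class GymlandingError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(GymlandingError):
    """A configuration value is outside its valid range."""


class MalformedFileError(GymlandingError):
    """A trial file does not match the expected schema or time base."""


class MetadataError(GymlandingError):
    """Trial metadata contains an unknown task/gaze token or bad value."""


class DatasetIntegrityError(GymlandingError):
    """Manifest inconsistency: missing files or duplicated trial keys."""


class NoFlightError(GymlandingError):
    """No flight phase could be found in an IMU record."""


class NoImpactError(GymlandingError):
    """No supra-threshold vertical-acceleration peak follows the last flight."""


class InsufficientDataError(GymlandingError):
    """A signal is too short for the requested operation."""


class NormalisationError(GymlandingError):
    """EMG normalisation is impossible (no kept AS trial for a participant/muscle)."""


class ImbalanceError(GymlandingError):
    """The study table is not balanced (missing subject x task x gaze cells)."""


class DegenerateSampleError(GymlandingError):
    """A statistical routine received a degenerate sample (e.g. zero variance)."""
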