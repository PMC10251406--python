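"""Exception hierarchy for dielmat.

Everything raised on bad scientific input derives from :class:`DielmatError`
so callers can catch the package's own failures separately from programming
errors.
"""


class DielmatError(ValueError):
    """Base class for all dielmat domain errors."""


class InvalidMeasurementError(DielmatError):
    """A delta value or isotope ratio outside its physical domain."""


class DegenerateCalibrationError(DielmatError):
    """Calibration pairs cannot define a correction line."""


class DegenerateEndMembersError(DielmatError):
    """Mixing end-members coincide; the mass balance is undefined."""


class ConfigError(DielmatError):
    """Inconsistent or incomplete configuration."""


class DegenerateProfileError(DielmatError):
    """A depth profile without usable vertical extent."""


class UndefinedPartitionError(DielmatError):
    """Profile integral is non-positive; a photic partition is undefined."""


class NoBoundaryError(DielmatError):
    """An irradiance profile never reaches the photic threshold."""


class UndefinedLossError(DielmatError):
    """Diel loss requested with non-positive earlier uptake."""


class IllConditionedError(DielmatError):
    """A mass-balance inversion too ill-conditioned to trust."""


class EmptySignalError(DielmatError):
    """All-zero ion intensities; no mass isotopomer distribution exists."""


class StabilityError(DielmatError):
    """Euler step too large for the simulated loss rate."""


class SchemaError(DielmatError):
    """An input table is missing required columns or has bad dtypes."""
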