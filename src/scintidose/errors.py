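"""Exception hierarchy shared across the package."""


class ScintidoseError(Exception):
    """Base class for all package errors."""


class TableFormatError(ScintidoseError):
    """A physics-table CSV is malformed (non-numeric, non-monotone, non-positive)."""


class EnergyRangeError(ScintidoseError, ValueError):
    """An energy lies outside the tabulated grid; extrapolation is refused."""


class ConfigError(ScintidoseError, ValueError):
    """An invalid detector/source/run configuration value."""


class CalibrationFailureError(ScintidoseError):
    """The two-peak search could not find two qualifying peaks."""


class InsufficientStatisticsError(CalibrationFailureError):
    """Calibration acquisition timed out with too few counts to be usable."""


class SaturationError(ScintidoseError, ValueError):
    """An observed count rate implies deadtime fraction >= 1 (not physical)."""


class UnreliableRateError(ScintidoseError):
    """Deadtime fraction beyond the correction guard cap; output unreliable."""


class DeviceStateError(ScintidoseError):
    """An operation requires device state that is absent (e.g. no calibration)."""
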