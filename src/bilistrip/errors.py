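"""Exception hierarchy.

Every error raised by the library derives from :class:`BilistripError`,
so callers can catch one base class at pipeline level while tests can
assert on the specific failure mode.
"""


class BilistripError(Exception):
    """Base class for all bilistrip errors."""


class PresetNotFoundError(BilistripError, KeyError):
    """An unknown light-source or response preset name was requested."""


class DegenerateSpectrumError(BilistripError, ValueError):
    """A spectrum carries no usable power for the requested operation."""


class NoOverlapError(BilistripError, ValueError):
    """Two spectra share no common wavelength range."""


class ConfigurationError(BilistripError, ValueError):
    """An invalid parameter value (negative sigma, non-positive exposure, ...)."""


class DomainError(BilistripError, ValueError):
    """An argument outside its physical domain (e.g. negative concentration)."""


class GeometryError(BilistripError, ValueError):
    """A region of interest does not fit the window or image."""


class EmptyROIError(BilistripError, ValueError):
    """A mask selects no pixels."""


class SingularDesignError(BilistripError, ValueError):
    """All concentrations equal; the calibration line is not identifiable."""


class InsufficientDataError(BilistripError, ValueError):
    """Too few records to fit a calibration line."""


class UndefinedRSquaredError(BilistripError, ZeroDivisionError):
    """Total variance is zero; the coefficient of determination is undefined."""


class ZeroDegreesOfFreedomError(BilistripError, ValueError):
    """Residual standard deviation requested with n <= 2."""


class UndefinedLimitError(BilistripError, ZeroDivisionError):
    """Detection limit requested for a flat (zero-slope) calibration."""
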