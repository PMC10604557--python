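"""Exception types raised across the package.

All inherit from :class:`SpecfingerError` so callers can catch pipeline
failures with a single except clause while tests can assert on the precise
failure mode.
"""


class SpecfingerError(Exception):
    """Base class for all package-specific errors."""


class DatasetFormatError(SpecfingerError):
    """Malformed dataset file: ragged rows, non-numeric or non-monotone grid."""


class LabelError(SpecfingerError):
    """Unknown class-label token."""


class GridError(SpecfingerError):
    """Wavenumber grids do not match, or a band center lies off the grid."""


class RegionError(SpecfingerError):
    """Requested wavenumber interval does not overlap the grid."""


class ConfigError(SpecfingerError):
    """Invalid configuration value (window/polyorder, bounds, fractions...)."""


class DegenerateInputError(SpecfingerError):
    """Input carries no usable signal (all-zero spectrum, constant response...)."""


class ConvergenceError(SpecfingerError):
    """An iterative algorithm failed to converge within its iteration cap."""


class EmptySeedError(SpecfingerError):
    """Peak seeding found no candidate bands above the prominence threshold."""
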