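"""Exception hierarchy for ratiospec.

Everything raised on purpose derives from :class:`RatioSpecError` so callers
can catch the package's own failures without swallowing programming errors.
"""


class RatioSpecError(Exception):
    """Base class for all ratiospec errors."""


class ParseError(RatioSpecError):
    """A spectrum file could not be parsed; the message names the offending row."""


class GridError(RatioSpecError):
    """Wavelength grid violation: duplicate, irregular, off-grid, or unrepresentable."""


class RangeError(RatioSpecError):
    """A requested wavelength window falls outside the available data."""


class MaskedSignalError(RatioSpecError):
    """A signal was requested at a wavelength masked by the division guard."""


class DegenerateRatioError(RatioSpecError):
    """Too few unmasked samples remain to form a usable ratio spectrum."""


class RankError(RatioSpecError):
    """Calibration input is rank-deficient (e.g. a single concentration level)."""


class InversionError(RatioSpecError):
    """A calibration model with zero slope cannot be inverted."""


class SelectionError(RatioSpecError):
    """No candidate wavelength satisfied the interferent-rejection constraint."""


class ConfigError(RatioSpecError):
    """A method or run configuration is inconsistent."""


class ExtrapolationWarning(UserWarning):
    """Predicted concentration lies outside the calibrated range."""
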