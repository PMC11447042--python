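"""Ratio spectra and the three selective transforms: RD, 1DD and MC.

The resolution principle for a two-component mixture under Beer-Lambert
additivity: divide the mixture spectrum pointwise by a standard spectrum of
the *interfering* analyte (the divisor). The interferent's contribution
becomes a wavelength-independent constant, while the target's contribution
remains wavelength-dependent and proportional to its concentration. Any
linear operation that annihilates constants then isolates the target:

* **RD** (ratio difference): amplitude difference between two wavelengths,
  ``P(l1) - P(l2)``.
* **1DD** (first derivative of the ratio spectrum): symmetric difference
  ``k * [P(l + dl) - P(l - dl)] / (2 dl)`` read at one wavelength.
* **MC** (mean centering): subtract the mean amplitude over a working
  window, read the centered value at one wavelength.

All three are linear in the sample spectrum, so calibration against
concentration is a straight line and mixture signals are additive.

Wavelengths where the divisor falls below a division guard ``epsilon`` are
masked (never emitted as infinities); masked samples propagate through the
transforms and reading a masked wavelength raises
:class:`~ratiospec.errors.MaskedSignalError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    ConfigError,
    DegenerateRatioError,
    GridError,
    MaskedSignalError,
    RangeError,
)
from .spectra import LOOKUP_ATOL, Spectrum

#: Default division guard, in AU. Divisor magnitudes below this are masked.
DEFAULT_EPSILON = 0.01


@dataclass
class RatioSpectrum:
    """A spectrum divided pointwise by a divisor spectrum.

    ``amplitudes`` are dimensionless ratios P(lambda); ``mask`` is True where
    the sample is valid (divisor above the guard) and False where it is
    masked. Masked amplitudes are stored as NaN and never used.
    """

    wavelengths: np.ndarray
    amplitudes: np.ndarray
    divisor_label: str = "divisor"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        # reuse Spectrum's grid validation
        probe = Spectrum(self.wavelengths, np.nan_to_num(self.amplitudes))
        self.wavelengths = probe.wavelengths
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.amplitudes)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.size != self.wavelengths.size:
            raise GridError("mask length does not match the grid")
        if not np.all(np.isfinite(self.amplitudes[self.mask])):
            raise GridError("unmasked amplitudes must be finite")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def n_unmasked(self) -> int:
        return int(np.count_nonzero(self.mask))

    def index_of(self, lam: float) -> int:
        i = int(round((lam - self.wavelengths[0]) / self.step))
        if 0 <= i < len(self) and abs(self.wavelengths[i] - lam) <= LOOKUP_ATOL:
            return i
        raise GridError(f"{lam} nm is not on the ratio-spectrum grid")

    def crop(self, lo: float, hi: float) -> "RatioSpectrum":
        if lo >= hi:
            raise RangeError(f"crop requires lo < hi, got {lo} >= {hi}")
        keep = (self.wavelengths >= lo - LOOKUP_ATOL) & (
            self.wavelengths <= hi + LOOKUP_ATOL
        )
        if np.count_nonzero(keep) < 3:
            raise RangeError(f"crop [{lo}, {hi}] nm leaves fewer than 3 samples")
        return RatioSpectrum(
            self.wavelengths[keep], self.amplitudes[keep],
            self.divisor_label, self.mask[keep],
        )


def amplitude_at(ratio: RatioSpectrum, lam: float) -> float:
    """Stored amplitude at an on-grid wavelength; masked points raise."""
    i = ratio.index_of(lam)
    if not ratio.mask[i]:
        raise MaskedSignalError(
            f"{lam} nm is masked (divisor below guard for {ratio.divisor_label})"
        )
    return float(ratio.amplitudes[i])


def ratio_spectrum(sample: Spectrum, divisor: Spectrum,
                   epsilon: float = DEFAULT_EPSILON) -> RatioSpectrum:
    """Divide ``sample`` pointwise by ``divisor`` with a division guard.

    If the grids differ, the divisor is linearly resampled onto the portion
    of the sample grid it covers. Samples where ``|A_divisor| < epsilon`` are
    masked. Fewer than 3 unmasked samples raises
    :class:`~ratiospec.errors.DegenerateRatioError`.
    """
    if epsilon <= 0:
        raise ConfigError(f"division guard epsilon must be > 0, got {epsilon}")
    if divisor.same_grid(sample):
        div = divisor
        smp = sample
    else:
        lo = max(sample.wavelengths[0], divisor.wavelengths[0])
        hi = min(sample.wavelengths[-1], divisor.wavelengths[-1])
        if lo >= hi:
            raise RangeError("sample and divisor spectra do not overlap")
        smp = sample.crop(lo, hi)
        div = divisor.resample(smp.wavelengths)

    mask = np.abs(div.absorbances) >= epsilon
    if np.count_nonzero(mask) < 3:
        raise DegenerateRatioError(
            f"only {int(np.count_nonzero(mask))} samples have divisor "
            f"magnitude >= {epsilon} AU"
        )
    amp = np.full(len(smp), np.nan)
    amp[mask] = smp.absorbances[mask] / div.absorbances[mask]
    label = "{}@{}".format(
        div.metadata.get("analyte", "divisor"),
        div.metadata.get("concentration", "?"),
    )
    return RatioSpectrum(smp.wavelengths, amp, label, mask)


def ratio_difference(ratio: RatioSpectrum, lambda1: float, lambda2: float) -> float:
    """Signed amplitude difference ``P(lambda1) - P(lambda2)``.

    For a sample containing only the divisor analyte the ratio spectrum is
    constant, so the difference vanishes — the RD selectivity principle.
    """
    return amplitude_at(ratio, lambda1) - amplitude_at(ratio, lambda2)


def first_derivative(ratio: RatioSpectrum, delta_lambda: float = 4.0,
                     scaling_factor: float = 10.0) -> RatioSpectrum:
    """First derivative of a ratio spectrum by symmetric differencing.

    ``D(l) = scaling_factor * [P(l + dl) - P(l - dl)] / (2 dl)`` at every
    interior point; the first and last ``delta_lambda`` of the range, and any
    point whose +-dl neighbours are masked, are masked in the output. The
    symmetric difference is exact for locally quadratic signals. The scaling
    factor is cosmetic (it cancels in calibration) but kept for comparability
    with instrument-software output.
    """
    if delta_lambda <= 0 or scaling_factor <= 0:
        raise ConfigError("delta_lambda and scaling_factor must be positive")
    shift = delta_lambda / ratio.step
    s = int(round(shift))
    if s < 1 or abs(shift - s) > 1e-9:
        raise GridError(
            f"delta_lambda {delta_lambda} nm is not a positive multiple of the "
            f"grid spacing {ratio.step} nm"
        )
    n = len(ratio)
    if n < 2 * s + 1:
        raise RangeError(
            f"need at least 2*delta_lambda of span: {n} samples < {2 * s + 1}"
        )
    amp = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    interior = slice(s, n - s)
    ok = ratio.mask[2 * s:] & ratio.mask[:-2 * s]
    deriv = (ratio.amplitudes[2 * s:] - ratio.amplitudes[:-2 * s]) / (2.0 * delta_lambda)
    amp[interior] = np.where(ok, scaling_factor * deriv, np.nan)
    mask[interior] = ok
    return RatioSpectrum(ratio.wavelengths, amp, ratio.divisor_label, mask)


def savgol_first_derivative(ratio: RatioSpectrum, window_length: int = 9,
                            polyorder: int = 2,
                            scaling_factor: float = 10.0) -> RatioSpectrum:
    """Savitzky-Golay first derivative: an optional smoother alternative.

    Not the default transform; provided for noisy spectra where plain
    differencing amplifies high-frequency noise.
    """
    if window_length % 2 == 0 or window_length < polyorder + 1:
        raise ConfigError("window_length must be odd and exceed polyorder")
    n = len(ratio)
    if n < window_length:
        raise RangeError(f"{n} samples is shorter than window {window_length}")
    half = window_length // 2
    filled = np.where(ratio.mask, ratio.amplitudes, 0.0)
    deriv = savgol_filter(filled, window_length, polyorder, deriv=1,
                          delta=ratio.step)
    mask = np.zeros(n, dtype=bool)
    # valid only where the full window is unmasked and away from the edges
    run = np.convolve(ratio.mask.astype(int), np.ones(window_length, dtype=int),
                      mode="same")
    mask[half:n - half] = run[half:n - half] == window_length
    amp = np.where(mask, scaling_factor * deriv, np.nan)
    return RatioSpectrum(ratio.wavelengths, amp, ratio.divisor_label, mask)


def mean_center(ratio: RatioSpectrum, lo: float, hi: float) -> RatioSpectrum:
    """Subtract the mean amplitude over ``[lo, hi]`` (unmasked samples only).

    The output is restricted to the window and has zero mean over its
    unmasked support; a constant ratio spectrum maps to all zeros, which is
    the MC selectivity principle.
    """
    window = ratio.crop(lo, hi)
    if window.n_unmasked < 3:
        raise DegenerateRatioError(
            f"mean centering window [{lo}, {hi}] nm has only "
            f"{window.n_unmasked} unmasked samples"
        )
    mean = float(np.mean(window.amplitudes[window.mask]))
    amp = np.where(window.mask, window.amplitudes - mean, np.nan)
    return RatioSpectrum(window.wavelengths, amp, window.divisor_label, window.mask)


# ---------------------------------------------------------------------------
# method configuration and dispatch
# ---------------------------------------------------------------------------

_METHODS = ("RD", "DD1", "MC")


@dataclass
class MethodConfig:
    """Per-method, per-analyte parameters for a selective signal.

    ``wavelengths`` is a pair (l1, l2) for RD and a single-element tuple for
    DD1 and MC. ``delta_lambda``/``scaling_factor`` apply to DD1 only and
    ``mc_range`` to MC only.
    """

    method: str
    analyte: str
    divisor_analyte: str
    divisor_concentration: float
    wavelengths: tuple
    delta_lambda: float = 4.0
    scaling_factor: float = 10.0
    mc_range: tuple = (200.0, 305.0)
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}, got {self.method!r}")
        wl = tuple(float(w) for w in np.atleast_1d(self.wavelengths))
        if self.method == "RD":
            if len(wl) != 2 or wl[0] == wl[1]:
                raise ConfigError("RD needs two distinct wavelengths")
        else:
            if len(wl) != 1:
                raise ConfigError(f"{self.method} needs exactly one wavelength")
        self.wavelengths = wl
        if self.method == "DD1" and (self.delta_lambda <= 0 or self.scaling_factor <= 0):
            raise ConfigError("DD1 requires delta_lambda > 0 and scaling_factor > 0")
        if self.method == "MC" and not self.mc_range[0] < self.mc_range[1]:
            raise ConfigError("MC range must satisfy lo < hi")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")

    @property
    def name(self) -> str:
        return f"{self.analyte}-{self.method}"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "analyte": self.analyte,
            "divisor_analyte": self.divisor_analyte,
            "divisor_concentration": self.divisor_concentration,
            "wavelengths": list(self.wavelengths),
            "delta_lambda": self.delta_lambda,
            "scaling_factor": self.scaling_factor,
            "mc_range": list(self.mc_range),
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MethodConfig":
        d = dict(data)
        d["wavelengths"] = tuple(d["wavelengths"])
        d["mc_range"] = tuple(d.get("mc_range", (200.0, 305.0)))
        return cls(**d)

    def with_wavelengths(self, wavelengths) -> "MethodConfig":
        return replace(self, wavelengths=tuple(np.atleast_1d(wavelengths)))


def transform(ratio: RatioSpectrum, config: MethodConfig) -> RatioSpectrum:
    """Apply the configured transform, returning the derived ratio spectrum.

    RD has no spectrum-to-spectrum transform (it is read directly from the
    ratio spectrum), so the input is returned unchanged.
    """
    if config.method == "RD":
        return ratio
    if config.method == "DD1":
        return first_derivative(ratio, config.delta_lambda, config.scaling_factor)
    return mean_center(ratio, *config.mc_range)


def method_signal(mixture: Spectrum, config: MethodConfig,
                  divisor: Spectrum) -> float:
    """Scalar selective signal of ``mixture`` for the configured method.

    Dispatches: RD -> ratio difference at (l1, l2); DD1 -> first derivative
    then amplitude at l; MC -> mean centering over ``mc_range`` then
    amplitude at l.
    """
    ratio = ratio_spectrum(mixture, divisor, config.epsilon)
    if config.method == "RD":
        return ratio_difference(ratio, *config.wavelengths)
    derived = transform(ratio, config)
    return amplitude_at(derived, config.wavelengths[0])


#: Canonical configurations for the six published method/analyte pairs of the
#: bisoprolol (BPL) / telmisartan (TST) assay. BPL methods use a 16 ug/mL TST
#: divisor; TST methods use a 10 ug/mL BPL divisor.
DEFAULT_CONFIGS: dict[str, MethodConfig] = {
    "BPL-RD": MethodConfig("RD", "BPL", "TST", 16.0, (210.0, 224.0)),
    "BPL-DD1": MethodConfig("DD1", "BPL", "TST", 16.0, (232.0,)),
    "BPL-MC": MethodConfig("MC", "BPL", "TST", 16.0, (223.0,)),
    "TST-RD": MethodConfig("RD", "TST", "BPL", 10.0, (255.0, 265.0)),
    "TST-DD1": MethodConfig("DD1", "TST", "BPL", 10.0, (243.0,)),
    "TST-MC": MethodConfig("MC", "TST", "BPL", 10.0, (245.0,)),
}
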