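"""Absorbance spectra on regular wavelength grids, with plain-text I/O.

Every downstream transform (ratio spectra, derivatives, mean centering)
assumes aligned, regularly spaced wavelength axes, so the :class:`Spectrum`
container enforces the grid invariants once, at construction:

* wavelengths strictly ascending,
* constant spacing (to within ``GRID_ATOL`` nm),
* at least three samples, absorbances the same length.

Files are two-column comma/tab-separated text (wavelength nm, absorbance AU)
with optional ``#`` comment lines; ``# key=value`` comments carry metadata.
This is the lowest-common-denominator benchtop UV-Vis export format.
Interpolation at I/O time is linear only, so any smoothing or differencing
remains attributable to the method modules.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import GridError, ParseError, RangeError

#: Maximum tolerated deviation from uniform grid spacing, in nm.
GRID_ATOL = 1e-9

#: Tolerance when matching a requested wavelength to a grid point, in nm.
LOOKUP_ATOL = 1e-6


@dataclass
class Spectrum:
    """A sampled absorbance curve on a regular, ascending wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelengths in nm, strictly ascending, regularly spaced.
    absorbances : array-like
        Absorbance in AU, same length as ``wavelengths``.
    metadata : dict, optional
        Free-form label map (e.g. ``analyte``, ``concentration``, ``replicate``).
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if w.ndim != 1 or a.ndim != 1:
            raise GridError("wavelengths and absorbances must be 1-D arrays")
        if w.size != a.size:
            raise GridError(
                f"length mismatch: {w.size} wavelengths vs {a.size} absorbances"
            )
        if w.size < 3:
            raise GridError(f"a spectrum needs at least 3 samples, got {w.size}")
        d = np.diff(w)
        if np.any(d == 0):
            dup = float(w[np.argmin(d)])
            raise GridError(f"duplicate wavelength {dup} nm")
        if np.any(d < 0):
            raise GridError("wavelengths must be strictly increasing")
        if float(np.ptp(d)) > GRID_ATOL:
            raise GridError(
                f"irregular wavelength spacing: range of steps {float(np.ptp(d)):.3g} nm "
                f"exceeds tolerance {GRID_ATOL:g} nm"
            )
        self.wavelengths = w
        self.absorbances = a

    # -- grid helpers -----------------------------------------------------

    @property
    def step(self) -> float:
        """Grid spacing in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def index_of(self, lam: float) -> int:
        """Index of the grid point at wavelength ``lam`` (nm).

        Raises :class:`GridError` if ``lam`` is not a grid point to within
        ``LOOKUP_ATOL``; derived signals are never silently interpolated.
        """
        i = int(round((lam - self.wavelengths[0]) / self.step))
        if 0 <= i < len(self) and abs(self.wavelengths[i] - lam) <= LOOKUP_ATOL:
            return i
        raise GridError(f"{lam} nm is not on the grid "
                        f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] "
                        f"step {self.step} nm")

    def absorbance_at(self, lam: float) -> float:
        return float(self.absorbances[self.index_of(lam)])

    # -- transforms -------------------------------------------------------

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Retain samples with ``lo <= wavelength <= hi`` (inclusive both ends)."""
        if lo >= hi:
            raise RangeError(f"crop requires lo < hi, got {lo} >= {hi}")
        keep = (self.wavelengths >= lo - LOOKUP_ATOL) & (
            self.wavelengths <= hi + LOOKUP_ATOL
        )
        n = int(np.count_nonzero(keep))
        if n == 0:
            raise RangeError(
                f"crop [{lo}, {hi}] nm does not overlap "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        if n < 3:
            raise RangeError(f"crop [{lo}, {hi}] nm leaves only {n} sample(s)")
        return Spectrum(self.wavelengths[keep], self.absorbances[keep],
                        dict(self.metadata))

    def resample(self, grid) -> "Spectrum":
        """Linear interpolation onto ``grid`` (nm); no extrapolation.

        Exact on piecewise-linear spectra and the identity on the native grid.
        """
        g = np.asarray(grid, dtype=float)
        if g.size and (g.min() < self.wavelengths[0] - LOOKUP_ATOL
                       or g.max() > self.wavelengths[-1] + LOOKUP_ATOL):
            raise RangeError(
                f"target grid [{g.min()}, {g.max()}] nm extends outside source "
                f"range [{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        a = np.interp(g, self.wavelengths, self.absorbances)
        return Spectrum(g, a, dict(self.metadata))

    def same_grid(self, other: "Spectrum") -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.wavelengths, other.wavelengths, atol=LOOKUP_ATOL, rtol=0)
        )

    # -- Beer-Lambert arithmetic ------------------------------------------

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if not isinstance(other, Spectrum):
            return NotImplemented
        if not self.same_grid(other):
            raise GridError("cannot add spectra on different grids")
        return Spectrum(self.wavelengths, self.absorbances + other.absorbances)

    def __mul__(self, scalar: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.absorbances * float(scalar),
                        dict(self.metadata))

    __rmul__ = __mul__


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def _split_row(line: str):
    if "," in line:
        return [p.strip() for p in line.split(",")]
    if "\t" in line:
        return [p.strip() for p in line.split("\t")]
    return line.split()


def read_spectrum(source) -> Spectrum:
    """Read a two-column (wavelength nm, absorbance AU) text table.

    ``source`` may be a path or an open text stream. Comma, tab or whitespace
    separated; ``#`` lines are comments, and ``# key=value`` comments populate
    the metadata map. An optional non-numeric header row is skipped. Rows are
    sorted ascending by wavelength before grid validation.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        name = getattr(source, "name", "<stream>")
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        name = os.fspath(source)

    metadata: dict = {}
    wavelengths: list[float] = []
    absorbances: list[float] = []
    header_seen = False
    for rownum, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
            continue
        parts = _split_row(line)
        if len(parts) < 2:
            raise ParseError(f"{name}, row {rownum}: expected 2 columns, got {len(parts)}")
        try:
            w, a = float(parts[0]), float(parts[1])
        except ValueError:
            if not header_seen and not wavelengths:
                header_seen = True  # tolerate one textual header row
                continue
            raise ParseError(
                f"{name}, row {rownum}: non-numeric cell in {parts[:2]!r}"
            ) from None
        wavelengths.append(w)
        absorbances.append(a)

    if len(wavelengths) < 3:
        raise ParseError(f"{name}: only {len(wavelengths)} data rows; need at least 3")
    order = np.argsort(wavelengths, kind="stable")
    w = np.asarray(wavelengths, dtype=float)[order]
    a = np.asarray(absorbances, dtype=float)[order]
    if np.any(np.diff(w) == 0):
        dup = float(w[np.argmin(np.diff(w))])
        raise GridError(f"{name}: duplicate wavelength {dup} nm")
    return Spectrum(w, a, metadata)


def write_spectrum(spectrum: Spectrum, destination) -> None:
    """Write a spectrum as CSV with metadata in ``# key=value`` comments.

    Values are written with 17 significant digits so that
    ``read_spectrum(write_spectrum(s))`` reproduces the arrays exactly.
    """
    own = not hasattr(destination, "write")
    fh = open(destination, "w", encoding="utf-8") if own else destination
    try:
        fh.write("# ratiospec spectrum\n")
        for key, value in spectrum.metadata.items():
            fh.write(f"# {key}={value}\n")
        fh.write("wavelength_nm,absorbance_au\n")
        for w, a in zip(spectrum.wavelengths, spectrum.absorbances):
            fh.write(f"{w:.17g},{a:.17g}\n")
    finally:
        if own:
            fh.close()


def spectrum_from_string(text: str) -> Spectrum:
    """Convenience wrapper: parse a spectrum from an in-memory string."""
    return read_spectrum(io.StringIO(text))
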