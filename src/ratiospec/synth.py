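"""Synthetic UV absorbance spectra for a two-component overlapped assay.

The generator emulates the geometry of the bisoprolol (BPL) / telmisartan
(TST) overlap with Gaussian absorption bands under Beer-Lambert additivity:

* a weak, narrow-band absorber ("BPL-like") peaking near 225 nm with a
  small long-wavelength tail band, negligible above ~290 nm;
* a strong, broad absorber ("TST-like") spanning roughly 200-340 nm with
  deep-UV, 236 nm and 296 nm bands.

Unit-concentration absorbances are sums of Gaussians, so mixtures are
exactly linear in concentration at zero noise. Noise is additive white
Gaussian on absorbance, optionally plus a per-spectrum constant baseline
offset; every stochastic operation takes an explicit seed (no global
generator state). Excipients of the tablet matrix (talc, starch, magnesium
stearate) are modeled as non-absorbing.

The band parameters are synthetic stand-ins — the true molar absorptivity
curves of the two drugs are not published numerically — so absolute slopes
and detection limits of the real assay are not reproduced, only the
structural and statistical behavior of the methods.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError
from .spectra import Spectrum, write_spectrum


def default_grid(step: float = 1.0) -> np.ndarray:
    """The working scan range, 200-400 nm inclusive."""
    n = int(round(200.0 / step)) + 1
    return np.linspace(200.0, 400.0, n)


@dataclass(frozen=True)
class ComponentProfile:
    """Gaussian-band absorptivity profile of one analyte.

    ``bands`` is a tuple of (center nm, width nm, height AU per ug/mL);
    the unit-concentration absorbance is the sum of the bands.
    """

    label: str
    bands: tuple

    def __post_init__(self) -> None:
        for center, width, height in self.bands:
            if width <= 0:
                raise ValueError(f"band width must be > 0, got {width}")
            if height < 0:
                raise ValueError(f"band height must be >= 0, got {height}")

    def unit_absorbance(self, grid) -> np.ndarray:
        g = np.asarray(grid, dtype=float)
        a = np.zeros_like(g)
        for center, width, height in self.bands:
            a += height * np.exp(-((g - center) ** 2) / (2.0 * width**2))
        return a


@dataclass(frozen=True)
class NoiseModel:
    """Additive instrument noise: white Gaussian on absorbance (AU).

    ``baseline_drift`` is the SD of a per-spectrum constant offset (AU),
    emulating slow baseline wander between scans; zero by default.
    """

    additive_sd: float = 0.0
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.baseline_drift < 0:
            raise ValueError("noise SDs must be >= 0")


def component_spectrum(profile: ComponentProfile, concentration: float,
                       grid=None) -> Spectrum:
    """Noise-free Beer-Lambert spectrum of one component.

    ``absorbance = concentration * unit_absorbance``; exactly linear in
    concentration.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(g, concentration * profile.unit_absorbance(g),
                    {"analyte": profile.label, "concentration": f"{concentration:g}"})


def simulate_mixture(profiles, concentrations, noise: NoiseModel | None = None,
                     grid=None, rng: np.random.Generator | None = None) -> Spectrum:
    """Sum of component spectra plus baseline offset and additive noise.

    The seeded generator comes from ``noise.seed`` unless an ``rng`` is
    passed explicitly (batch generators thread one rng through many calls to
    stay deterministic). Metadata records the true concentrations and seed.
    """
    profiles = list(profiles)
    concentrations = [float(c) for c in concentrations]
    if len(profiles) != len(concentrations):
        raise GridError("profiles and concentrations must have equal length")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    a = np.zeros_like(g)
    meta = {}
    for profile, conc in zip(profiles, concentrations):
        if conc < 0:
            raise ValueError(f"concentration must be >= 0, got {conc}")
        a = a + conc * profile.unit_absorbance(g)
        meta[f"true_{profile.label}"] = f"{conc:g}"
    if noise is not None and (noise.additive_sd > 0 or noise.baseline_drift > 0):
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        if noise.baseline_drift > 0:
            a = a + rng.normal(0.0, noise.baseline_drift)
        if noise.additive_sd > 0:
            a = a + rng.normal(0.0, noise.additive_sd, size=g.size)
        meta["seed"] = str(noise.seed)
        meta["noise_sd"] = f"{noise.additive_sd:g}"
    return Spectrum(g, a, meta)


def default_profiles() -> tuple[ComponentProfile, ComponentProfile]:
    """Bundled BPL-like and TST-like profiles reproducing the assay geometry.

    Constructed so that (a) the two zero-order spectra overlap substantially
    below 290 nm, (b) the TST-like absorber is strong across the BPL RD pair
    (210/224 nm), and (c) the BPL-like absorber is negligible above 290 nm
    while keeping enough of a tail band that a 10 ug/mL BPL divisor stays
    above the 0.01 AU division guard through the TST analysis wavelengths.
    Band heights are sized so that 0.002 AU additive noise propagates to
    sub-percent concentration RSDs at the published working ranges.
    """
    bpl_like = ComponentProfile(
        "BPL",
        bands=(
            (202.0, 8.0, 0.040),   # deep-UV end absorption
            (225.5, 6.5, 0.120),   # main aromatic band, maximum near 225 nm
            (275.0, 13.0, 0.016),  # weak tail; keeps a 10 ug/mL divisor above
                                   # the 0.01 AU guard across the MC window
        ),
    )
    tst_like = ComponentProfile(
        "TST",
        bands=(
            (206.0, 12.0, 0.065),  # deep-UV edge
            (236.0, 18.0, 0.042),  # mid band overlapping the BPL maximum
            (296.0, 28.0, 0.048),  # long-wavelength band, BPL-free region
        ),
    )
    return bpl_like, tst_like


# ---------------------------------------------------------------------------
# full validation-study generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Geometry of the published validation study.

    Defaults: 8-level calibrations over 2-20 (BPL) and 4-32 (TST) ug/mL,
    five synthetic mixture ratios spanning the tablet ratio, 3 replicates x
    3 days, and a tablet base of 2 + 16 ug/mL (the 5 mg / 40 mg fixed-dose
    ratio) with 4/8/12 ug/mL spikes of each analyte.
    """

    bpl_levels: tuple = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0)
    tst_levels: tuple = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0)
    mixtures: tuple = ((4.0, 32.0), (3.5, 28.0), (3.0, 24.0),
                       (2.5, 20.0), (2.0, 16.0))
    replicates: int = 3
    days: int = 3
    tablet: tuple = (2.0, 16.0)
    spikes: tuple = (4.0, 8.0, 12.0)


def generate_validation_study(design: StudyDesign, noise: NoiseModel,
                              outdir, profiles=None,
                              grid=None) -> pd.DataFrame:
    """Write a spectra directory plus manifest for a full validation study.

    Produces per-analyte calibration standards (noise-free: calibrations are
    built from standards measured under instrument-averaged conditions),
    noisy mixture spectra (replicates x days), and a tablet base plus spiked
    tablet spectra for standard addition. Returns the manifest, which is
    also written as ``manifest.csv``. Deterministic for a given seed.
    """
    os.makedirs(outdir, exist_ok=True)
    bpl, tst = default_profiles() if profiles is None else profiles
    rng = np.random.default_rng(noise.seed)
    rows = []

    def emit(name, spectrum, **fields):
        path = os.path.join(outdir, name)
        write_spectrum(spectrum, path)
        rows.append({"file": name, **fields})

    for analyte, profile, other, levels in (
        ("BPL", bpl, tst, design.bpl_levels),
        ("TST", tst, bpl, design.tst_levels),
    ):
        for conc in levels:
            s = component_spectrum(profile, conc, grid)
            emit(f"cal_{analyte}_{conc:g}.csv", s, role="calibration",
                 analyte=analyte, bpl=conc if analyte == "BPL" else 0.0,
                 tst=conc if analyte == "TST" else 0.0, replicate=1, day=1)

    for i, (c_bpl, c_tst) in enumerate(design.mixtures, start=1):
        for day in range(1, design.days + 1):
            for rep in range(1, design.replicates + 1):
                s = simulate_mixture((bpl, tst), (c_bpl, c_tst), noise,
                                     grid, rng=rng)
                emit(f"mix{i}_d{day}_r{rep}.csv", s, role="mixture",
                     analyte="both", bpl=c_bpl, tst=c_tst,
                     replicate=rep, day=day)

    t_bpl, t_tst = design.tablet
    base = simulate_mixture((bpl, tst), (t_bpl, t_tst), noise, grid, rng=rng)
    emit("tablet_base.csv", base, role="tablet_base", analyte="both",
         bpl=t_bpl, tst=t_tst, replicate=1, day=1, added=0.0)
    # standard addition: both analytes are co-spiked at each level
    for j, spike in enumerate(design.spikes, start=1):
        for rep in range(1, design.replicates + 1):
            s = simulate_mixture((bpl, tst),
                                 (t_bpl + spike, t_tst + spike),
                                 noise, grid, rng=rng)
            emit(f"spike{j}_r{rep}.csv", s, role="spiked", analyte="both",
                 bpl=t_bpl + spike, tst=t_tst + spike,
                 replicate=rep, day=1, added=spike)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest
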