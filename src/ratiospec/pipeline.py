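"""End-to-end assay pipeline: calibrate, quantify, validate.

Glue between the synthetic generator (or spectra read from disk) and the
method/calibration/validation layers. Functions here operate either on
in-memory objects (profiles, spectra) or on a study directory written by
:func:`ratiospec.synth.generate_validation_study`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, fit_calibration, predict_concentration
from .ratio import DEFAULT_CONFIGS, MethodConfig, method_signal
from .reference import MIXTURE_LEVELS
from .spectra import Spectrum, read_spectrum
from .synth import (
    ComponentProfile,
    NoiseModel,
    component_spectrum,
    default_profiles,
    simulate_mixture,
)


def divisor_for(config: MethodConfig, profiles=None) -> Spectrum:
    """Noise-free divisor spectrum prescribed by a method configuration."""
    bpl, tst = default_profiles() if profiles is None else profiles
    by_label = {bpl.label: bpl, tst.label: tst}
    profile = by_label[config.divisor_analyte]
    return component_spectrum(profile, config.divisor_concentration)


def build_calibrations(configs=None, profiles=None, levels=None,
                       noise: NoiseModel | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> dict[str, CalibrationModel]:
    """Fit calibration models for each method from synthetic standards.

    ``levels`` maps analyte label to its concentration series; defaults to
    the published working ranges (2-20 and 4-32 ug/mL, 8 levels each).
    Standards are noise-free unless a noise model is given.
    """
    configs = dict(DEFAULT_CONFIGS) if configs is None else configs
    bpl, tst = default_profiles() if profiles is None else profiles
    by_label = {bpl.label: bpl, tst.label: tst}
    if levels is None:
        levels = {bpl.label: (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 20.0),
                  tst.label: (4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0)}
    models: dict[str, CalibrationModel] = {}
    for name, config in configs.items():
        divisor = divisor_for(config, (bpl, tst))
        profile = by_label[config.analyte]
        points = []
        for conc in levels[config.analyte]:
            if noise is None:
                standard = component_spectrum(profile, conc)
            else:
                standard = simulate_mixture([profile], [conc], noise, rng=rng)
            points.append((conc, method_signal(standard, config, divisor)))
        models[name] = fit_calibration(points, method_config=config)
    return models


def quantify(spectrum: Spectrum, models: dict[str, CalibrationModel],
             profiles=None, warn_extrapolation: bool = False) -> dict[str, float]:
    """Predicted concentration of each model's analyte in one mixture."""
    out = {}
    for name, model in models.items():
        config = model.method_config
        divisor = divisor_for(config, profiles)
        signal = method_signal(spectrum, config, divisor)
        out[name] = predict_concentration(model, signal,
                                          warn_extrapolation=warn_extrapolation)
    return out


def recovery_study(noise_sd: float, n_replicates: int, seed: int,
                   mixtures=MIXTURE_LEVELS, configs=None,
                   profiles=None) -> pd.DataFrame:
    """Simulate repeated mixture measurements and tabulate %R per method.

    Calibrations are built noise-free; each replicate draws fresh additive
    noise on the mixture spectrum. Returns one row per
    (mixture level, replicate, method) with the found concentration and %R.
    """
    configs = dict(DEFAULT_CONFIGS) if configs is None else configs
    bpl, tst = default_profiles() if profiles is None else profiles
    models = build_calibrations(configs, (bpl, tst))
    noise = NoiseModel(additive_sd=noise_sd, seed=seed)
    rng = np.random.default_rng(seed)
    truth = {bpl.label: 0, tst.label: 1}
    rows = []
    for c_bpl, c_tst in mixtures:
        for rep in range(1, n_replicates + 1):
            spectrum = simulate_mixture((bpl, tst), (c_bpl, c_tst), noise,
                                        rng=rng)
            found = quantify(spectrum, models, (bpl, tst))
            for name, conc in found.items():
                analyte = models[name].method_config.analyte
                taken = (c_bpl, c_tst)[truth[analyte]]
                rows.append({"bpl": c_bpl, "tst": c_tst, "replicate": rep,
                             "method": name, "analyte": analyte,
                             "taken": taken, "found": conc,
                             "recovery": 100.0 * conc / taken})
    return pd.DataFrame(rows)


def load_study(study_dir) -> tuple[pd.DataFrame, dict[str, Spectrum]]:
    """Read a study directory (manifest + spectra) back into memory."""
    manifest = pd.read_csv(os.path.join(study_dir, "manifest.csv"))
    spectra = {row.file: read_spectrum(os.path.join(study_dir, row.file))
               for row in manifest.itertuples()}
    return manifest, spectra


def calibrations_from_study(manifest: pd.DataFrame,
                            spectra: dict[str, Spectrum],
                            configs=None) -> dict[str, CalibrationModel]:
    """Fit the method calibrations from a study's calibration standards.

    Divisor spectra are taken from the calibration standards themselves
    (the divisor concentration must be one of the calibration levels).
    """
    configs = dict(DEFAULT_CONFIGS) if configs is None else configs
    cal = manifest[manifest["role"] == "calibration"]
    models = {}
    for name, config in configs.items():
        div_rows = cal[(cal["analyte"] == config.divisor_analyte)
                       & (np.isclose(cal[config.divisor_analyte.lower()],
                                     config.divisor_concentration))]
        if div_rows.empty:
            raise KeyError(
                f"no {config.divisor_analyte} calibration standard at "
                f"{config.divisor_concentration} ug/mL to use as divisor"
            )
        divisor = spectra[div_rows.iloc[0]["file"]]
        points = []
        for row in cal[cal["analyte"] == config.analyte].itertuples():
            conc = getattr(row, config.analyte.lower())
            points.append((conc, method_signal(spectra[row.file], config, divisor)))
        models[name] = fit_calibration(points, method_config=config)
    return models


def quantify_study(manifest: pd.DataFrame, spectra: dict[str, Spectrum],
                   models: dict[str, CalibrationModel],
                   roles=("mixture", "tablet_base", "spiked")) -> pd.DataFrame:
    """Predict concentrations for every non-calibration spectrum in a study."""
    configs = {name: m.method_config for name, m in models.items()}
    divisors = {}
    cal = manifest[manifest["role"] == "calibration"]
    for name, config in configs.items():
        div_rows = cal[(cal["analyte"] == config.divisor_analyte)
                       & (np.isclose(cal[config.divisor_analyte.lower()],
                                     config.divisor_concentration))]
        divisors[name] = spectra[div_rows.iloc[0]["file"]]
    rows = []
    for row in manifest[manifest["role"].isin(roles)].itertuples():
        for name, model in models.items():
            config = model.method_config
            signal = method_signal(spectra[row.file], config, divisors[name])
            conc = predict_concentration(model, signal, warn_extrapolation=False)
            taken = getattr(row, config.analyte.lower())
            rows.append({
                "file": row.file, "role": row.role, "method": name,
                "analyte": config.analyte, "replicate": row.replicate,
                "day": row.day, "taken": taken, "found": conc,
                "added": getattr(row, "added", np.nan),
                "recovery": 100.0 * conc / taken if taken > 0 else np.nan,
            })
    return pd.DataFrame(rows)
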