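"""Linear calibration: fit, diagnostics, detection limits, inverse prediction.

The signal of each ratio-spectra method is linear in concentration, so the
calibration model is ordinary least squares of signal on concentration
(unweighted; negative slopes are legitimate and kept signed). Detection and
quantitation limits follow the ICH Q2 residual-SD convention::

    LOD = 3.3 * sigma / |S|        LOQ = 10 * sigma / |S|

with ``sigma`` the residual standard deviation of the calibration line
(n - 2 degrees of freedom) and ``S`` the slope. The SD-of-intercept variant
of sigma is available via ``sigma="intercept"`` but is not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ExtrapolationWarning, InversionError, RankError
from .ratio import MethodConfig

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass
class CalibrationModel:
    """Fitted straight line ``signal = slope * concentration + intercept``."""

    slope: float
    intercept: float
    residual_sd: float
    r_squared: float
    n_points: int
    conc_range: tuple
    method_config: MethodConfig | None = None
    intercept_sd: float = field(default=np.nan)

    def signal_of(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(points, method_config: MethodConfig | None = None,
                    sigma: str = "residual") -> CalibrationModel:
    """Ordinary least squares of signal on concentration.

    Parameters
    ----------
    points : sequence of (concentration, signal) pairs
        At least 3 points covering at least 2 distinct concentrations.
    sigma : {"residual", "intercept"}
        Which standard deviation feeds LOD/LOQ: the residual SD of the line
        (default) or the standard error of the intercept.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise RankError(f"need >= 3 (concentration, signal) points, got {pts.shape}")
    conc, sig = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise RankError("all concentrations are equal; the line is not identifiable")

    res = stats.linregress(conc, sig)
    n = conc.size
    residuals = sig - (res.slope * conc + res.intercept)
    residual_sd = float(np.sqrt(np.sum(residuals**2) / (n - 2)))
    r_squared = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    intercept_sd = float(res.intercept_stderr)
    used_sd = residual_sd if sigma == "residual" else intercept_sd
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=float(used_sd),
        r_squared=r_squared,
        n_points=int(n),
        conc_range=(float(conc.min()), float(conc.max())),
        method_config=method_config,
        intercept_sd=intercept_sd,
    )


def lod(model: CalibrationModel) -> float:
    """Limit of detection, ``3.3 * sigma / |S|`` (ug/mL)."""
    if model.slope == 0:
        raise InversionError("zero slope: detection limit is undefined")
    return LOD_FACTOR * model.residual_sd / abs(model.slope)


def loq(model: CalibrationModel) -> float:
    """Limit of quantitation, ``10 * sigma / |S|`` (ug/mL)."""
    if model.slope == 0:
        raise InversionError("zero slope: quantitation limit is undefined")
    return LOQ_FACTOR * model.residual_sd / abs(model.slope)


def lod_to_loq(lod_value: float) -> float:
    """Convert an LOD to the LOQ implied by the 3.3/10 factor pair."""
    return lod_value * LOQ_FACTOR / LOD_FACTOR


def predict_concentration(model: CalibrationModel, signal: float,
                          warn_extrapolation: bool = True) -> float:
    """Invert the calibration line: ``(signal - intercept) / slope``.

    Signals mapping outside the calibrated concentration range still return
    a value but emit :class:`~ratiospec.errors.ExtrapolationWarning` — QC
    users need the number together with the flag.
    """
    if model.slope == 0:
        raise InversionError("zero slope: the calibration cannot be inverted")
    conc = (signal - model.intercept) / model.slope
    lo, hi = model.conc_range
    tol = 1e-9 * max(1.0, abs(lo), abs(hi))  # ignore float-boundary overshoot
    if warn_extrapolation and not (lo - tol <= conc <= hi + tol):
        warnings.warn(
            f"predicted concentration {conc:.4g} ug/mL is outside the "
            f"calibrated range [{lo}, {hi}] ug/mL",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(conc)


def calibration_report(models: dict[str, CalibrationModel]) -> pd.DataFrame:
    """Tabulate fitted models: one row per method, regression + limits."""
    rows = []
    for name, m in models.items():
        cfg = m.method_config
        rows.append({
            "method": name,
            "wavelengths_nm": "/".join(f"{w:g}" for w in cfg.wavelengths) if cfg else "",
            "range_ug_ml": f"{m.conc_range[0]:g}-{m.conc_range[1]:g}",
            "slope": m.slope,
            "intercept": m.intercept,
            "r_squared": m.r_squared,
            "residual_sd": m.residual_sd,
            "lod_ug_ml": lod(m),
            "loq_ug_ml": loq(m),
            "n_points": m.n_points,
        })
    return pd.DataFrame(rows).set_index("method")
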