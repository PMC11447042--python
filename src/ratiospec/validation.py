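"""Method-validation statistics: recovery, precision, comparison tests, scans.

Implements the ICH-style validation layer of a two-component
spectrophotometric assay:

* percent recovery and recovery summaries (accuracy, repeatability and
  intermediate precision as RSD),
* standard-addition recovery (selectivity against the tablet matrix),
* pooled-variance two-sample t test and variance-ratio F test for comparing
  a candidate method with a reference method,
* wavelength-selection and divisor-selection scans that automate the
  "check linearity at every candidate wavelength" step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import fit_calibration
from .errors import DegenerateRatioError, RatioSpecError, SelectionError
from .ratio import (
    MethodConfig,
    RatioSpectrum,
    amplitude_at,
    first_derivative,
    mean_center,
    ratio_difference,
    ratio_spectrum,
    transform,
)
from .spectra import Spectrum

ALPHA = 0.05


# ---------------------------------------------------------------------------
# recovery arithmetic
# ---------------------------------------------------------------------------

def percent_recovery(found: float, taken: float) -> float:
    """``100 * found / taken`` (%R); ``taken`` must be positive."""
    if taken <= 0:
        raise ValueError(f"taken concentration must be > 0, got {taken}")
    return 100.0 * found / taken


def standard_addition_recovery(base_found: float, spiked_found: float,
                               added: float) -> float:
    """Recovery of the *added* amount: ``100 * (spiked - base) / added``.

    The matrix-selectivity check: known analyte is spiked into a real
    (tablet) sample and only the increment is scored, so a matrix bias on
    the base sample cancels.
    """
    if added <= 0:
        raise ValueError(f"added concentration must be > 0, got {added}")
    return 100.0 * (spiked_found - base_found) / added


@dataclass
class RecoverySummary:
    recoveries: tuple
    mean_recovery: float
    sd: float
    rsd: float
    n: int


def summarize_recoveries(recoveries) -> RecoverySummary:
    """Mean, sample SD (n-1 df) and RSD = 100*SD/mean of %R values."""
    values = tuple(float(v) for v in recoveries)
    if len(values) < 2:
        raise ValueError(f"need at least 2 recoveries, got {len(values)}")
    arr = np.asarray(values)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return RecoverySummary(values, mean, sd, 100.0 * sd / mean, len(values))


# ---------------------------------------------------------------------------
# method-comparison tests
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """t and/or F comparison of two methods at alpha = 0.05.

    ``f_stat`` follows the larger/smaller variance convention, so it is
    always >= 1; ``t_stat`` is reported as |t|. Either part may be None when
    only one test was computed.
    """

    t_stat: float | None = None
    df_t: int | None = None
    t_critical: float | None = None
    f_stat: float | None = None
    df_f: tuple | None = None
    f_critical: float | None = None
    infinite_t: bool = False

    @property
    def t_significant(self) -> bool:
        return self.t_stat is not None and self.t_stat > self.t_critical

    @property
    def f_significant(self) -> bool:
        return self.f_stat is not None and self.f_stat > self.f_critical


def two_sample_t(mean_a: float, sd_a: float, n_a: int,
                 mean_b: float, sd_b: float, n_b: int,
                 alpha: float = ALPHA) -> ComparisonResult:
    """Pooled-variance two-sample t test from summary statistics.

    ``t = |mean_a - mean_b| / (s_p * sqrt(1/n_a + 1/n_b))`` with
    ``s_p^2 = [(n_a-1) sd_a^2 + (n_b-1) sd_b^2] / (n_a + n_b - 2)`` and
    df = n_a + n_b - 2. With both SDs zero, t is 0 for equal means and the
    ``infinite_t`` flag is set for unequal means.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n_a + n_b - 2
    t_crit = float(stats.t.ppf(1 - alpha / 2, df))
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = abs(mean_a - mean_b)
    if pooled_var == 0:
        if diff == 0:
            return ComparisonResult(t_stat=0.0, df_t=df, t_critical=t_crit)
        return ComparisonResult(t_stat=math.inf, df_t=df, t_critical=t_crit,
                                infinite_t=True)
    t = diff / math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    return ComparisonResult(t_stat=float(t), df_t=df, t_critical=t_crit)


def f_ratio(var_a: float, var_b: float, n_a: int = 5, n_b: int = 5,
            alpha: float = ALPHA) -> ComparisonResult:
    """Variance-ratio F test: larger variance over smaller, so F >= 1."""
    if var_a <= 0 or var_b <= 0:
        raise ValueError("variances must be > 0")
    if var_a >= var_b:
        f, df = var_a / var_b, (n_a - 1, n_b - 1)
    else:
        f, df = var_b / var_a, (n_b - 1, n_a - 1)
    f_crit = float(stats.f.ppf(1 - alpha, *df))
    return ComparisonResult(f_stat=float(f), df_f=df, f_critical=f_crit)


def compare_methods(values_a, values_b, alpha: float = ALPHA) -> ComparisonResult:
    """Full t + F comparison from two sets of raw determinations."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    t_part = two_sample_t(a.mean(), a.std(ddof=1), a.size,
                          b.mean(), b.std(ddof=1), b.size, alpha)
    f_part = f_ratio(a.var(ddof=1), b.var(ddof=1), a.size, b.size, alpha)
    return ComparisonResult(
        t_stat=t_part.t_stat, df_t=t_part.df_t, t_critical=t_part.t_critical,
        f_stat=f_part.f_stat, df_f=f_part.df_f, f_critical=f_part.f_critical,
        infinite_t=t_part.infinite_t,
    )


# ---------------------------------------------------------------------------
# wavelength selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    chosen: tuple
    scores: pd.DataFrame


def _candidate_signal(ratio: RatioSpectrum, method: str, candidate,
                      delta_lambda: float, scaling_factor: float,
                      mc_range) -> float:
    if method == "RD":
        return ratio_difference(ratio, candidate[0], candidate[1])
    if method == "DD1":
        return amplitude_at(
            first_derivative(ratio, delta_lambda, scaling_factor), candidate[0]
        )
    return amplitude_at(mean_center(ratio, *mc_range), candidate[0])


def select_signal_wavelengths(target_set, interferent_set, method: str,
                              candidates, rejection_threshold: float | None = None,
                              delta_lambda: float = 4.0,
                              scaling_factor: float = 10.0,
                              mc_range=(200.0, 305.0)) -> SelectionResult:
    """Score candidate analysis wavelengths and pick the best.

    Parameters
    ----------
    target_set, interferent_set : sequence of (concentration, RatioSpectrum)
        Calibration-level ratio spectra of the target analyte and of the
        interferent, both built with the *same* divisor.
    method : {"RD", "DD1", "MC"}
        RD scans all ordered pairs of ``candidates``; DD1 and MC scan single
        wavelengths.
    candidates : sequence of wavelengths (nm)
    rejection_threshold : float, optional
        Maximum tolerated |interferent signal|. When omitted it is computed
        per candidate as 1% of the |target signal| at the middle calibration
        level, so "rejection" always means small relative to the working
        signal of that candidate.

    Scoring: each candidate gets (r2 of the target calibration, |slope|,
    max |interferent signal| across its levels). The winner maximizes r2
    (rounded to 10 decimal places to make floating-point ties explicit)
    subject to the rejection constraint, tie-broken by larger |slope|. The
    full score table is returned for audit.
    """
    targets = [(float(c), r) for c, r in target_set]
    interferents = [(float(c), r) for c, r in interferent_set]
    if len(targets) < 3:
        raise SelectionError("need >= 3 target calibration levels")
    if method == "RD":
        cands = [(float(a), float(b)) for i, a in enumerate(candidates)
                 for b in list(candidates)[i + 1:]]
    else:
        cands = [(float(a),) for a in candidates]

    mid = sorted(c for c, _ in targets)[len(targets) // 2]
    rows = []
    for cand in cands:
        try:
            tgt = [(c, _candidate_signal(r, method, cand, delta_lambda,
                                         scaling_factor, mc_range))
                   for c, r in targets]
            rej = max(abs(_candidate_signal(r, method, cand, delta_lambda,
                                            scaling_factor, mc_range))
                      for _, r in interferents)
        except RatioSpecError:
            continue  # masked candidate: skipped, not scored
        model = fit_calibration(tgt)
        mid_signal = abs(model.signal_of(mid))
        threshold = (rejection_threshold if rejection_threshold is not None
                     else 0.01 * mid_signal)
        rows.append({
            "candidate": cand,
            "r_squared": model.r_squared,
            "abs_slope": abs(model.slope),
            "interferent_max_abs_signal": rej,
            "rejection_threshold": threshold,
            "passes_rejection": rej <= threshold,
        })
    if not rows:
        raise SelectionError("no candidate wavelength could be scored "
                             "(all masked or degenerate)")
    scores = pd.DataFrame(rows)
    passing = scores[scores["passes_rejection"]]
    if passing.empty:
        best = scores.nsmallest(5, "interferent_max_abs_signal")
        raise SelectionError(
            "no candidate passed interferent rejection; closest failures:\n"
            + best.to_string(index=False)
        )
    ranked = passing.assign(r2_key=passing["r_squared"].round(10)).sort_values(
        ["r2_key", "abs_slope"], ascending=[False, False], kind="stable"
    )
    chosen = ranked.iloc[0]["candidate"]
    return SelectionResult(tuple(chosen), scores)


# ---------------------------------------------------------------------------
# divisor selection
# ---------------------------------------------------------------------------

def divisor_scan(candidate_divisors, calibration_set, config: MethodConfig) -> pd.DataFrame:
    """Rank candidate divisor spectra for one method configuration.

    ``calibration_set`` is a sequence of (concentration, Spectrum) standards
    of the target analyte. Each divisor is scored by the calibration r2 of
    the method signal and by its noise amplification — the mean of
    ``1/|A_divisor|`` over the unmasked working range, which is how additive
    absorbance noise propagates into ratio amplitude noise. Ranking is by r2
    (rounded to 10 decimals) then by *lower* noise amplification; divisors
    that cannot form a usable ratio are excluded with a diagnostic row.
    """
    if len(candidate_divisors) < 1:
        raise ValueError("need at least one candidate divisor")
    rows = []
    for divisor in candidate_divisors:
        label = "{}@{}".format(divisor.metadata.get("analyte", "divisor"),
                               divisor.metadata.get("concentration", "?"))
        try:
            points = []
            amps = []
            for conc, spectrum in calibration_set:
                ratio = ratio_spectrum(spectrum, divisor, config.epsilon)
                if config.method == "RD":
                    sig = ratio_difference(ratio, *config.wavelengths)
                else:
                    sig = amplitude_at(transform(ratio, config),
                                       config.wavelengths[0])
                points.append((float(conc), sig))
                amps.append(ratio)
            model = fit_calibration(points)
            # noise amplification over the unmasked working range of the divisor
            ref = amps[0]
            div_on_grid = divisor.resample(ref.wavelengths)
            valid = ref.mask
            noise_amp = float(np.mean(1.0 / np.abs(div_on_grid.absorbances[valid])))
            rows.append({"divisor": label, "r_squared": model.r_squared,
                         "noise_amplification": noise_amp,
                         "excluded": False, "diagnostic": ""})
        except (DegenerateRatioError, RatioSpecError) as exc:
            rows.append({"divisor": label, "r_squared": np.nan,
                         "noise_amplification": np.nan,
                         "excluded": True, "diagnostic": str(exc)})
    table = pd.DataFrame(rows)
    usable = table[~table["excluded"]].assign(
        r2_key=lambda d: d["r_squared"].round(10)
    ).sort_values(["r2_key", "noise_amplification"],
                  ascending=[False, True], kind="stable").drop(columns="r2_key")
    excluded = table[table["excluded"]]
    ranked = pd.concat([usable, excluded], ignore_index=True)
    ranked.insert(0, "rank", [*range(1, len(usable) + 1),
                              *[np.nan] * len(excluded)])
    return ranked
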