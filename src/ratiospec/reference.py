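"""Published validation figures for the bisoprolol/telmisartan assay.

These are the printed regression parameters, per-level recoveries and
method-comparison statistics of the published UV ratio-spectra assay of
bisoprolol fumarate (BPL) and telmisartan (TST). They serve as arithmetic
ground truth: the package's summary statistics, detection-limit
conversions and comparison tests are checked by recomputing each printed
summary from its printed inputs.

Keys are ``(analyte, method)`` with analyte in {"BPL", "TST"} and method in
{"RD", "DD1", "MC"}. Concentrations are ug/mL; recoveries are %R.

Known inconsistency: the published t statistic for BPL-DD1 (0.106) does not
follow from the printed means and SDs under the pooled-variance formula
(which gives ~0.363); that single cell is excluded from numerical checks.
"""

from __future__ import annotations

METHODS = ("RD", "DD1", "MC")
ANALYTES = ("BPL", "TST")
COLUMNS = tuple((a, m) for a in ANALYTES for m in METHODS)

#: Regression and sensitivity parameters, one column per (analyte, method).
CALIBRATION_PARAMETERS: dict = {
    ("BPL", "RD"): {"wavelengths": (210.0, 224.0), "range": (2.0, 20.0),
                    "slope": 0.0110, "intercept": 0.0206, "r_squared": 0.9999,
                    "lod": 0.2433, "loq": 0.7372},
    ("BPL", "DD1"): {"wavelengths": (232.0,), "range": (2.0, 20.0),
                     "slope": 0.0315, "intercept": 0.0617, "r_squared": 0.9999,
                     "lod": 0.3128, "loq": 0.9478},
    ("BPL", "MC"): {"wavelengths": (223.0,), "range": (2.0, 20.0),
                    "slope": 0.0243, "intercept": 0.0363, "r_squared": 0.9999,
                    "lod": 0.4056, "loq": 1.2291},
    ("TST", "RD"): {"wavelengths": (255.0, 265.0), "range": (4.0, 32.0),
                    "slope": 0.5845, "intercept": 0.2964, "r_squared": 0.9997,
                    "lod": 0.5965, "loq": 1.8076},
    ("TST", "DD1"): {"wavelengths": (243.0,), "range": (4.0, 32.0),
                     "slope": 2.2634, "intercept": 1.8242, "r_squared": 0.9998,
                     "lod": 0.9141, "loq": 2.7700},
    ("TST", "MC"): {"wavelengths": (245.0,), "range": (4.0, 32.0),
                    "slope": 2.2829, "intercept": 1.7896, "r_squared": 0.9995,
                    "lod": 0.7066, "loq": 2.1411},
}

#: The five synthetic-mixture composition levels (BPL, TST) in ug/mL.
MIXTURE_LEVELS = ((4.0, 32.0), (3.5, 28.0), (3.0, 24.0), (2.5, 20.0), (2.0, 16.0))


def _table(columns, means, rsds):
    return {
        col: {"recoveries": col_values, "mean": mean, "rsd": rsd}
        for col, col_values, mean, rsd in zip(COLUMNS, columns, means, rsds)
    }


#: Accuracy / repeatability (intra-day): per-level mean %R at the five
#: mixture levels, with the printed summary mean and RSD.
ACCURACY_INTRADAY = _table(
    columns=(
        (100.24, 99.80, 99.94, 100.39, 100.51),
        (100.19, 100.15, 99.87, 100.79, 100.59),
        (99.98, 99.65, 99.94, 100.72, 100.78),
        (99.24, 98.92, 100.65, 100.13, 99.68),
        (99.47, 99.93, 100.31, 100.05, 100.31),
        (99.33, 99.33, 99.75, 99.47, 99.69),
    ),
    means=(100.17, 100.32, 100.21, 99.72, 100.01, 99.51),
    rsds=(0.298, 0.366, 0.505, 0.692, 0.346, 0.198),
)

#: Intermediate (inter-day) precision.
PRECISION_INTERDAY = _table(
    columns=(
        (100.22, 99.65, 100.56, 99.96, 101.08),
        (100.04, 101.18, 101.28, 100.89, 100.54),
        (100.44, 99.54, 101.03, 100.24, 101.33),
        (100.63, 99.03, 101.10, 100.80, 100.77),
        (100.30, 101.31, 100.88, 99.60, 101.45),
        (99.24, 100.69, 100.27, 98.94, 100.81),
    ),
    means=(100.29, 100.79, 100.51, 100.46, 100.71, 99.99),
    rsds=(0.549, 0.503, 0.697, 0.818, 0.759, 0.852),
)

#: Laboratory-prepared tablet assay.
TABLET_ASSAY = _table(
    columns=(
        (100.18, 99.62, 100.01, 100.22, 100.52),
        (100.12, 100.56, 100.45, 100.94, 100.71),
        (100.01, 100.01, 100.09, 100.62, 100.71),
        (99.95, 99.78, 100.48, 101.19, 99.96),
        (99.84, 100.52, 100.35, 99.87, 100.61),
        (99.24, 99.91, 99.76, 99.25, 99.98),
    ),
    means=(100.11, 100.56, 100.29, 100.27, 100.24, 99.63),
    rsds=(0.330, 0.305, 0.346, 0.573, 0.359, 0.359),
)

#: Standard addition to the tablet base (2 + 16 ug/mL), spikes of 4/8/12
#: ug/mL; recovery of the added amount.
STANDARD_ADDITION = {
    "taken": (2.0, 16.0),
    "added": (4.0, 8.0, 12.0),
    **_table(
        columns=(
            (99.56, 100.53, 100.40),
            (99.46, 99.65, 99.71),
            (99.32, 100.47, 100.16),
            (99.37, 98.49, 98.74),
            (100.59, 99.47, 100.69),
            (98.76, 99.27, 99.87),
        ),
        means=(100.16, 99.61, 99.99, 98.87, 100.25, 99.30),
        rsds=(0.525, 0.134, 0.593, 0.459, 0.676, 0.560),
    ),
}

#: Statistical comparison against the reference area-under-curve method:
#: summary statistics (n = 5 each) plus the printed t and F values.
METHOD_COMPARISON = {
    "BPL": {
        "methods": {
            "RD": {"mean": 100.04, "sd": 0.469, "variance": 0.220, "n": 5,
                   "t": 1.160, "f": 2.719},
            "DD1": {"mean": 100.66, "sd": 0.505, "variance": 0.255, "n": 5,
                    "t": 0.106, "f": 2.347, "t_inconsistent": True},
            "MC": {"mean": 100.22, "sd": 0.398, "variance": 0.158, "n": 5,
                   "t": 0.752, "f": 3.789},
        },
        "reference": {"mean": 100.51, "sd": 0.774, "variance": 0.599, "n": 5},
    },
    "TST": {
        "methods": {
            "RD": {"mean": 100.31, "sd": 0.543, "variance": 0.294, "n": 5,
                   "t": 0.665, "f": 1.482},
            "DD1": {"mean": 100.45, "sd": 0.542, "variance": 0.294, "n": 5,
                    "t": 1.053, "f": 1.484},
            "MC": {"mean": 99.74, "sd": 0.650, "variance": 0.422, "n": 5,
                   "t": 0.757, "f": 1.034},
        },
        "reference": {"mean": 100.05, "sd": 0.660, "variance": 0.436, "n": 5},
    },
    "t_critical": 2.306,   # t(0.975, df=8)
    "f_critical": 6.388,   # F(0.95; 4, 4)
}
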