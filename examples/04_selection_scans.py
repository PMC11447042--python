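"""Automate the wavelength-pair and divisor choices for the RD method.

Scans every wavelength pair on a 1 nm grid for the BPL ratio-difference
signal, scoring calibration linearity, sensitivity and interferent
rejection; then ranks candidate TST divisor concentrations by noise
amplification (the mean of 1/|A_divisor| over the working range).
"""

import numpy as np

from ratiospec import DEFAULT_CONFIGS, component_spectrum, default_profiles, ratio_spectrum
from ratiospec.validation import divisor_scan, select_signal_wavelengths

bpl, tst = default_profiles()
divisor = component_spectrum(tst, 16.0)

target_set = [(c, ratio_spectrum(component_spectrum(bpl, c), divisor))
              for c in (2.0, 6.0, 10.0, 14.0, 20.0)]
interferent_set = [(c, ratio_spectrum(component_spectrum(tst, c), divisor))
                   for c in (4.0, 16.0, 32.0)]

candidates = [float(w) for w in np.arange(205.0, 296.0, 1.0)]
result = select_signal_wavelengths(target_set, interferent_set, "RD", candidates)
print(f"scanned {len(result.scores)} wavelength pairs")
print(f"chosen RD pair for BPL: {result.chosen} nm")
top = result.scores.nlargest(3, "abs_slope")[
    ["candidate", "r_squared", "abs_slope", "interferent_max_abs_signal"]]
print(top.to_string(index=False))

print("\ndivisor ranking for BPL-RD (noise-free: r2 ties, noise "
      "amplification decides):")
ranking = divisor_scan([component_spectrum(tst, c) for c in (12.0, 16.0, 20.0)],
                       [(c, component_spectrum(bpl, c))
                        for c in (2.0, 8.0, 14.0, 20.0)],
                       DEFAULT_CONFIGS["BPL-RD"])
print(ranking.to_string(index=False))
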