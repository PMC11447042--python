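"""Wavelength-pair and divisor selection scans against brute-force oracles."""

import numpy as np
import pytest

from ratiospec import (
    MethodConfig,
    RatioSpectrum,
    amplitude_at,
    component_spectrum,
    first_derivative,
    mean_center,
    ratio_difference,
    ratio_spectrum,
)
from ratiospec.errors import SelectionError
from ratiospec.validation import divisor_scan, select_signal_wavelengths


def build_sets(profiles, analyte="BPL"):
    bpl, tst = profiles
    target, interferent = (bpl, tst) if analyte == "BPL" else (tst, bpl)
    div_conc = 16.0 if analyte == "BPL" else 10.0
    divisor = component_spectrum(interferent, div_conc)
    t_levels = (2.0, 6.0, 10.0, 14.0, 20.0)
    i_levels = (4.0, 16.0, 32.0)
    target_set = [(c, ratio_spectrum(component_spectrum(target, c), divisor))
                  for c in t_levels]
    interferent_set = [(c, ratio_spectrum(component_spectrum(interferent, c),
                                          divisor)) for c in i_levels]
    return target_set, interferent_set


def oracle_rd_search(target_set, interferent_set, candidates):
    """Independent exhaustive search over all wavelength pairs.

    Re-implements the documented scoring rule with plain loops and
    numpy.polyfit, sharing no code with the implementation under scan.
    """
    best = None
    for i, l1 in enumerate(candidates):
        for l2 in candidates[i + 1:]:
            sig = [ratio_difference(r, l1, l2) for _, r in target_set]
            conc = [c for c, _ in target_set]
            slope, intercept = np.polyfit(conc, sig, 1)
            pred = np.polyval([slope, intercept], conc)
            ss_res = float(np.sum((np.asarray(sig) - pred) ** 2))
            ss_tot = float(np.sum((np.asarray(sig) - np.mean(sig)) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            rej = max(abs(ratio_difference(r, l1, l2))
                      for _, r in interferent_set)
            mid_c = sorted(conc)[len(conc) // 2]
            threshold = 0.01 * abs(slope * mid_c + intercept)
            if rej > threshold:
                continue
            key = (round(r2, 10), abs(slope))
            if best is None or key > best[0]:
                best = (key, (l1, l2))
    return best[1] if best else None


class TestWavelengthSelection:
    def test_rd_pair_matches_exhaustive_oracle(self, profiles):
        target_set, interferent_set = build_sets(profiles, "BPL")
        candidates = [float(w) for w in np.arange(205.0, 296.0, 1.0)]
        result = select_signal_wavelengths(target_set, interferent_set, "RD",
                                           candidates)
        oracle = oracle_rd_search(target_set, interferent_set, candidates)
        assert result.chosen == oracle
        # interferent is fully rejected at the chosen pair (constant cancels)
        row = result.scores[result.scores["candidate"] == result.chosen]
        assert float(row["interferent_max_abs_signal"].iloc[0]) < 1e-9

    def test_chosen_pair_straddles_ratio_extremum(self, profiles):
        """The winning RD pair brackets the target ratio-spectrum extremum."""
        target_set, interferent_set = build_sets(profiles, "BPL")
        candidates = [float(w) for w in np.arange(205.0, 296.0, 1.0)]
        result = select_signal_wavelengths(target_set, interferent_set, "RD",
                                           candidates)
        _, top = target_set[-1]
        valid = top.wavelengths[top.mask]
        peak = float(valid[np.argmax(top.amplitudes[top.mask])])
        l1, l2 = result.chosen
        assert l1 <= peak <= l2 or l2 <= peak <= l1

    @pytest.mark.parametrize("method", ["DD1", "MC"])
    def test_single_wavelength_methods_match_loop_oracle(self, profiles, method):
        target_set, interferent_set = build_sets(profiles, "TST")
        candidates = [float(w) for w in np.arange(235.0, 290.0, 1.0)]
        result = select_signal_wavelengths(target_set, interferent_set, method,
                                           candidates)

        def signal(r, lam):
            if method == "DD1":
                return amplitude_at(first_derivative(r, 4.0, 10.0), lam)
            return amplitude_at(mean_center(r, 200.0, 305.0), lam)

        best = None
        for lam in candidates:
            sig = [signal(r, lam) for _, r in target_set]
            conc = [c for c, _ in target_set]
            slope, intercept = np.polyfit(conc, sig, 1)
            r2 = np.corrcoef(conc, sig)[0, 1] ** 2
            rej = max(abs(signal(r, lam)) for _, r in interferent_set)
            mid = sorted(conc)[len(conc) // 2]
            if rej > 0.01 * abs(slope * mid + intercept):
                continue
            key = (round(float(r2), 10), abs(slope))
            if best is None or key > best[0]:
                best = (key, (lam,))
        assert result.chosen == best[1]

    def test_single_candidate_returned(self, profiles):
        target_set, interferent_set = build_sets(profiles, "BPL")
        result = select_signal_wavelengths(target_set, interferent_set, "MC",
                                           [223.0])
        assert result.chosen == (223.0,)
        assert len(result.scores) == 1

    def test_all_masked_candidates_raise(self, profiles):
        w = np.arange(200.0, 300.0)
        mask = w < 250
        levels = []
        for c in (1.0, 2.0, 3.0):
            amp = np.where(mask, c * w / 100, np.nan)
            levels.append((c, RatioSpectrum(w, amp, mask=mask)))
        with pytest.raises(SelectionError):
            select_signal_wavelengths(levels, levels[:1] * 3, "DD1",
                                      [280.0, 290.0])


class TestDivisorScan:
    def test_noise_free_ranking_by_noise_amplification(self, profiles):
        """With r2 tied at 1, higher-concentration divisors win because the
        mean of 1/|A_divisor| falls as the divisor grows."""
        bpl, tst = profiles
        cfg = MethodConfig("RD", "BPL", "TST", 16.0, (210.0, 224.0))
        candidates = [component_spectrum(tst, c) for c in (12.0, 16.0, 20.0)]
        cal = [(c, component_spectrum(bpl, c)) for c in (2.0, 8.0, 14.0, 20.0)]
        table = divisor_scan(candidates, cal, cfg)
        ranked = table[~table["excluded"]]
        assert list(ranked["divisor"]) == ["TST@20", "TST@16", "TST@12"]
        assert ranked["noise_amplification"].is_monotonic_increasing
        assert np.allclose(ranked["r_squared"], 1.0)

    def test_single_candidate_is_rank_one(self, profiles):
        bpl, tst = profiles
        cfg = MethodConfig("RD", "BPL", "TST", 16.0, (210.0, 224.0))
        table = divisor_scan([component_spectrum(tst, 16.0)],
                             [(c, component_spectrum(bpl, c))
                              for c in (2.0, 10.0, 20.0)], cfg)
        assert table.iloc[0]["rank"] == 1

    def test_zero_divisor_excluded_with_diagnostic(self, profiles, grid):
        from ratiospec import Spectrum

        bpl, tst = profiles
        cfg = MethodConfig("RD", "BPL", "TST", 16.0, (210.0, 224.0))
        dead = Spectrum(grid, np.zeros_like(grid), {"analyte": "TST",
                                                    "concentration": "0"})
        table = divisor_scan([dead, component_spectrum(tst, 16.0)],
                             [(c, component_spectrum(bpl, c))
                              for c in (2.0, 10.0, 20.0)], cfg)
        dead_row = table[table["divisor"] == "TST@0"].iloc[0]
        assert bool(dead_row["excluded"])
        assert dead_row["diagnostic"] != ""
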