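"""Spectral parameterisation: aperiodic fits, peak extraction, flattening."""

import numpy as np
import pytest

from aperiodic_ei.spectral import Spectrum
from aperiodic_ei.specparam import (SpecparamSettings, fit_aperiodic, fit_model,
                                    flatten_spectrum, gaussian,
                                    largest_peak_in_band, PeakParams)
from conftest import grid_search_aperiodic

FREQS = np.arange(1.0, 101.0)


def make_spectrum(logp, freqs=FREQS):
    return Spectrum(np.asarray(freqs, dtype=float), 10.0 ** np.asarray(logp))


class TestFitAperiodic:
    def test_exact_power_law(self):
        s = Spectrum(FREQS, FREQS ** -2.0)
        fit = fit_aperiodic(s, (30, 100))
        assert fit.exponent == pytest.approx(2.0, abs=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_flat_spectrum_zero_exponent(self):
        s = Spectrum(FREQS, np.full(FREQS.size, 3.7))
        fit = fit_aperiodic(s, (30, 100))
        assert fit.exponent == pytest.approx(0.0, abs=1e-6)

    def test_knee_spectrum_matches_grid_search_oracle(self):
        s = Spectrum(FREQS, 1.0 / (10.0 + FREQS ** 1.5))
        fit = fit_aperiodic(s, (1, 100), mode="knee")
        assert fit.knee == pytest.approx(10.0, abs=1e-3)
        assert fit.exponent == pytest.approx(1.5, abs=1e-3)
        b, k, chi = grid_search_aperiodic(FREQS, np.log10(s.power), mode="knee")
        assert fit.exponent == pytest.approx(chi, abs=1e-3)
        assert fit.knee == pytest.approx(k, abs=0.5)

    def test_noiseless_fits_match_grid_search(self):
        rng = np.random.default_rng(3)
        for chi in (0.5, 1.0, 2.0, 3.0):
            b0 = rng.uniform(-1, 1)
            s = make_spectrum(b0 - chi * np.log10(FREQS))
            fit = fit_aperiodic(s, (30, 100))
            bg, _, chig = grid_search_aperiodic(
                FREQS[29:], np.log10(s.power[29:]), mode="fixed")
            assert fit.exponent == pytest.approx(chig, abs=1e-3)
            assert fit.offset == pytest.approx(bg, abs=1e-3)

    def test_knee_mode_on_kneeless_spectrum_matches_fixed(self):
        s = Spectrum(FREQS, 10.0 ** (1.2 - 1.8 * np.log10(FREQS)))
        fixed = fit_aperiodic(s, (30, 100), mode="fixed")
        knee = fit_aperiodic(s, (30, 100), mode="knee")
        assert knee.knee <= 1e-3
        assert knee.exponent == pytest.approx(fixed.exponent, abs=1e-3)

    def test_robust_fit_ignores_large_peak(self):
        logp = 0.5 - 1.5 * np.log10(FREQS) + gaussian(FREQS, 20, 0.8, 3)
        fit = fit_aperiodic(make_spectrum(logp), (5, 100))
        assert fit.exponent == pytest.approx(1.5, abs=0.08)

    def test_nonpositive_power_rejected(self):
        s = Spectrum(FREQS, np.r_[0.0, np.ones(99)], flattened=True)
        with pytest.raises(ValueError):
            fit_aperiodic(s, (1, 100))

    def test_bad_range_rejected(self):
        s = Spectrum(FREQS, FREQS ** -1.0)
        with pytest.raises(ValueError):
            fit_aperiodic(s, (50, 30))


class TestScaleInvariance:
    def test_fixed_mode_rescaling_shifts_only_offset(self):
        rng = np.random.default_rng(11)
        logp = -1.2 * np.log10(FREQS) + gaussian(FREQS, 22, 0.4, 2.5) \
            + rng.normal(0, 0.02, FREQS.size)
        s1 = make_spectrum(logp)
        c = 37.5
        s2 = Spectrum(FREQS, s1.power * c)
        m1 = fit_model(s1, (1, 100))
        m2 = fit_model(s2, (1, 100))
        # mathematically exact invariance; numerically limited by the
        # path-dependence of the iterative least-squares solvers
        assert m2.aperiodic.exponent == pytest.approx(m1.aperiodic.exponent,
                                                      abs=5e-8)
        assert m2.aperiodic.offset - m1.aperiodic.offset == pytest.approx(
            np.log10(c), abs=5e-8)
        assert len(m1.peaks) == len(m2.peaks)
        for p1, p2 in zip(m1.peaks, m2.peaks):
            assert p2.cf == pytest.approx(p1.cf, abs=5e-8)
            assert p2.pw == pytest.approx(p1.pw, abs=5e-8)


class TestFitModel:
    def test_pure_power_law_yields_no_peaks(self):
        s = Spectrum(FREQS, FREQS ** -1.5)
        m = fit_model(s, (30, 100))
        assert m.peaks == []
        assert m.aperiodic.exponent == pytest.approx(1.5, abs=1e-4)
        assert m.r2 == pytest.approx(1.0, abs=1e-6)

    def test_single_peak_recovery_over_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            logp = -1.5 * np.log10(FREQS) + gaussian(FREQS, 20, 0.5, 2) \
                + rng.normal(0, 0.01, FREQS.size)
            m = fit_model(make_spectrum(logp), (1, 100))
            peak = largest_peak_in_band(m, (13, 35))
            ok = (peak is not None and abs(peak.cf - 20) <= 1.0
                  and abs(peak.pw - 0.5) <= 0.1
                  and abs(m.aperiodic.exponent - 1.5) <= 0.05)
            hits += ok
        assert hits >= 19

    def test_two_peaks_recovered_sorted_by_cf(self):
        rng = np.random.default_rng(7)
        logp = (-1.2 * np.log10(FREQS) + gaussian(FREQS, 20, 0.5, 2.5)
                + gaussian(FREQS, 60, 0.3, 3.0) + rng.normal(0, 0.01, FREQS.size))
        m = fit_model(make_spectrum(logp), (1, 100))
        cfs = [p.cf for p in m.peaks]
        assert cfs == sorted(cfs)
        big = [p for p in m.peaks if p.pw > 0.15]
        assert len(big) == 2
        assert big[0].cf == pytest.approx(20, abs=1.0)
        assert big[1].cf == pytest.approx(60, abs=1.0)
        assert big[0].pw == pytest.approx(0.5, abs=0.1)
        assert big[1].pw == pytest.approx(0.3, abs=0.1)


class TestFlatten:
    def test_flattening_own_model_gives_zero(self):
        s = Spectrum(FREQS, FREQS ** -2.0)
        ap = fit_aperiodic(s, (1, 100))
        flat = flatten_spectrum(s, ap)
        assert flat.flattened
        np.testing.assert_allclose(flat.power, 0.0, atol=1e-6)

    def test_log_bump_passes_through_exactly(self):
        s = Spectrum(FREQS, FREQS ** -1.0)
        ap = fit_aperiodic(s, (1, 100))
        bumped = Spectrum(FREQS, s.power * 10 ** np.where(FREQS == 40, 0.5, 0.0))
        flat0 = flatten_spectrum(s, ap)
        flat1 = flatten_spectrum(bumped, ap)
        diff = flat1.power - flat0.power
        assert diff[FREQS == 40][0] == pytest.approx(0.5, abs=1e-12)
        assert np.all(np.abs(diff[FREQS != 40]) < 1e-12)

    def test_flatten_unflatten_roundtrip(self):
        rng = np.random.default_rng(2)
        logp = 0.3 - 1.3 * np.log10(FREQS) + rng.normal(0, 0.05, FREQS.size)
        s = make_spectrum(logp)
        ap = fit_aperiodic(s, (1, 100))
        flat = flatten_spectrum(s, ap)
        recovered = flat.power + ap.evaluate(s.frequencies)
        np.testing.assert_allclose(recovered, logp, atol=1e-12)

    def test_grid_outside_fit_range_rejected(self):
        s = Spectrum(FREQS, FREQS ** -1.0)
        ap = fit_aperiodic(s, (30, 100))
        with pytest.raises(ValueError):
            flatten_spectrum(s, ap)


class TestLargestPeakInBand:
    MODEL = None

    def make(self, peaks):
        s = Spectrum(FREQS, FREQS ** -1.0)
        m = fit_model(s, (1, 100))
        object.__setattr__  # keep linters quiet
        m.peaks = [PeakParams(*p) for p in peaks]
        return m

    def test_picks_largest_in_band(self):
        m = self.make([(20, 0.5, 3), (28, 0.7, 4), (60, 1.0, 5)])
        assert largest_peak_in_band(m, (13, 35)).cf == 28

    def test_none_when_band_empty(self):
        m = self.make([(60, 1.0, 5)])
        assert largest_peak_in_band(m, (13, 35)) is None

    def test_tie_breaks_to_lower_cf(self):
        m = self.make([(18, 0.5, 3), (30, 0.5, 3)])
        assert largest_peak_in_band(m, (13, 35)).cf == 18
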