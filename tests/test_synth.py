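"""Synthetic generators: spectral shape, phase locking, determinism."""

import numpy as np
import pytest
from scipy import signal as sps

from aperiodic_ei.spectral import morlet_power, time_average_psd
from aperiodic_ei.specparam import fit_aperiodic, fit_model, largest_peak_in_band
from aperiodic_ei.synth import (PatientCohortConfig, SynthConfig,
                                add_oscillations, gen_patient_cohort,
                                gen_patient_dataset, gen_phase_locked_spikes,
                                gen_powerlaw_noise, gen_rodent_dataset)
from aperiodic_ei.spike_state import count_spikes_per_epoch
from conftest import welch_spectrum

FS = 2048.0


def loglog_slope(x, fs, band=(30, 100)):
    s = welch_spectrum(x, fs)
    m = (s.frequencies >= band[0]) & (s.frequencies <= band[1])
    coef = np.polyfit(np.log10(s.frequencies[m]), np.log10(s.power[m]), 1)
    return coef[0]


class TestPowerlawNoise:
    def test_white_noise_has_zero_slope(self):
        slopes = [loglog_slope(gen_powerlaw_noise(0.0, FS, 100.0, s), FS)
                  for s in range(5)]
        assert abs(np.mean(slopes)) < 0.1

    def test_chi_two_slope(self):
        slopes = [loglog_slope(gen_powerlaw_noise(2.0, FS, 100.0, s), FS)
                  for s in range(5)]
        assert np.mean(slopes) == pytest.approx(-2.0, abs=0.1)

    def test_seed_determinism(self):
        a = gen_powerlaw_noise(1.5, FS, 10.0, seed=42)
        b = gen_powerlaw_noise(1.5, FS, 10.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_unit_variance(self):
        x = gen_powerlaw_noise(1.0, FS, 30.0, seed=0)
        assert x.std() == pytest.approx(1.0, abs=1e-9)

    def test_exponent_estimates_unbiased_across_chis(self):
        # fixed-mode fit at 30-100 Hz should recover chi without systematic bias
        for chi in (0.5, 1.0, 2.0, 3.0):
            errs = []
            for seed in range(12):
                x = gen_powerlaw_noise(chi, FS, 100.0, seed=seed)
                fit = fit_aperiodic(welch_spectrum(x, FS, f_max=110), (30, 100))
                errs.append(fit.exponent - chi)
            assert abs(np.mean(errs)) < 0.05


class TestAddOscillations:
    def test_injected_peak_recovered_by_model_fit(self):
        x = gen_powerlaw_noise(1.5, FS, 100.0, seed=1)
        x = add_oscillations(x, FS, [(20.0, 0.5, 2.0)], seed=2)
        m = fit_model(welch_spectrum(x, FS, f_max=95), (1, 90))
        peak = largest_peak_in_band(m, (13, 35))
        assert peak is not None
        assert peak.cf == pytest.approx(20.0, abs=1.0)

    def test_empty_peak_list_with_slow_only_adds_sinusoid(self):
        x = gen_powerlaw_noise(1.0, FS, 20.0, seed=3)
        y = add_oscillations(x, FS, [], slow_freq=1.0, slow_amp=2.0, seed=4)
        t = np.arange(x.size) / FS
        np.testing.assert_allclose(y - x, 2.0 * np.cos(2 * np.pi * t),
                                   atol=1e-12)

    def test_no_peaks_no_slow_is_identity(self):
        x = gen_powerlaw_noise(1.0, FS, 20.0, seed=5)
        np.testing.assert_array_equal(add_oscillations(x, FS, [], seed=6), x)


class TestPhaseLockedSpikes:
    def test_unmodulated_train_is_poisson_like(self):
        # Fano factor of epoch counts ~ 1 for a homogeneous Poisson process
        train = gen_phase_locked_spikes(1.0, 100.0, (20.0, 0.0), seed=8)
        counts = count_spikes_per_epoch(train, 100.0)
        fano = counts.var() / counts.mean()
        assert fano == pytest.approx(1.0, abs=0.2)

    def test_total_count_near_poisson_mean(self):
        r0, dur = 15.0, 200.0
        train = gen_phase_locked_spikes(1.0, dur, (r0, 0.9), seed=9)
        expect = r0 * dur
        assert abs(train.n_spikes - expect) <= 3 * np.sqrt(expect)

    def test_antiphase_trains_anticorrelated(self):
        a = gen_phase_locked_spikes(1.0, 100.0, (15.0, 1.0), 0.0, seed=10)
        b = gen_phase_locked_spikes(1.0, 100.0, (15.0, 1.0), np.pi, seed=11,
                                    unit_id="u1")
        ca = count_spikes_per_epoch(a, 100.0)
        cb = count_spikes_per_epoch(b, 100.0)
        assert np.corrcoef(ca, cb)[0, 1] < 0

    def test_overmodulation_rejected(self):
        with pytest.raises(ValueError):
            gen_phase_locked_spikes(1.0, 10.0, (10.0, 1.5))


class TestRodentDataset:
    def test_seed_determinism(self):
        cfg = SynthConfig(seed=4, duration_s=10.0, fs=512.0, n_animals=2,
                          lfp_per_animal=(1,), units_per_animal=(1,))
        r1, t1, _ = gen_rodent_dataset(cfg)
        r2, t2, _ = gen_rodent_dataset(cfg)
        np.testing.assert_array_equal(r1[0].data, r2[0].data)
        np.testing.assert_array_equal(t1[0][0].times_s, t2[0][0].times_s)

    def test_study_condition_channel_and_unit_counts(self):
        recs, trains, truth = gen_rodent_dataset(
            SynthConfig(seed=1, duration_s=5.0, fs=512.0))
        assert len(recs) == 8
        assert sum(r.n_channels for r in recs) == 28
        stn_units = sum(1 for tr in trains for t in tr if "stn" in t.unit_id)
        assert stn_units == 20

    def test_inverted_state_exponents_rejected(self):
        with pytest.raises(ValueError, match="chi_high"):
            gen_rodent_dataset(SynthConfig(chi_high=2.0, chi_low=1.0))

    def test_units_pass_isolation_qc(self):
        _, trains, _ = gen_rodent_dataset(
            SynthConfig(seed=2, duration_s=30.0, fs=512.0, n_animals=2))
        assert all(t.passes_qc for tr in trains for t in tr)


class TestPatientDataset:
    def test_condition_exponents_recovered(self):
        # mean over seeds: the 40-90 Hz fit recovers both condition exponents
        errs_a, errs_b = [], []
        for seed in range(6):
            rec_a, rec_b, _ = gen_patient_dataset(1.2, 1.5, seed=seed,
                                                  mains_amp=0.0)
            fit_a = fit_aperiodic(welch_spectrum(rec_a.data[0], rec_a.fs,
                                                 f_max=95), (40, 90))
            fit_b = fit_aperiodic(welch_spectrum(rec_b.data[0], rec_b.fs,
                                                 f_max=95), (40, 90))
            errs_a.append(fit_a.exponent - 1.2)
            errs_b.append(fit_b.exponent - 1.5)
        assert abs(np.mean(errs_a)) < 0.1
        assert abs(np.mean(errs_b)) < 0.1
        # the ON-OFF exponent increase is recovered in sign and size
        assert np.mean(np.array(errs_b) - np.array(errs_a)) + 0.3 == pytest.approx(
            0.3, abs=0.1)

    def test_dbs_plateau_biases_high_range_fit_low(self):
        _, rec_on, _ = gen_patient_dataset(
            1.2, 1.5, seed=2, dbs_b={"plateau_level": 1.0})
        tf = morlet_power(rec_on.data[0], rec_on.fs, 5, 90)
        from aperiodic_ei.spectral import interpolate_mains
        psd = interpolate_mains(time_average_psd(tf, norm_band=(5, 90)))
        low = fit_aperiodic(psd, (10, 50))
        high = fit_aperiodic(psd, (40, 90))
        assert high.exponent < low.exponent - 0.5

    def test_cohort_is_paired_and_deterministic(self):
        cfg = PatientCohortConfig.meds(seed=3)
        cfg.n_hemispheres = 2
        cfg.duration_s = 10.0
        p1, t1 = gen_patient_cohort(cfg)
        p2, t2 = gen_patient_cohort(cfg)
        np.testing.assert_array_equal(p1[0][0].data, p2[0][0].data)
        assert t1 == t2
        assert len(p1) == 2

    def test_cohort_effect_sizes_follow_study_conditions(self):
        cfg = PatientCohortConfig.dbs(seed=0)
        assert cfg.n_hemispheres == 26
        assert cfg.delta_chi_mean == pytest.approx(0.30)
        cfg2 = PatientCohortConfig.meds(seed=0)
        assert cfg2.n_hemispheres == 30
        assert cfg2.delta_chi_mean == pytest.approx(0.15)
        _, truth = gen_patient_cohort(cfg2)
        deltas = [h["chi_on"] - h["chi_off"] for h in truth["hemispheres"]]
        assert np.mean(deltas) == pytest.approx(0.15, abs=0.15)
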