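"""ON vs OFF 130 Hz stimulation, and why the fit range drops to 10-50 Hz.

During high-frequency stimulation the spectrum develops a plateau above
~50 Hz (band-limited artefact noise plus tones at half the stimulation
frequency and its harmonics).  Fitting the exponent at 40-90 Hz would read
falsely low; restricting to 10-50 Hz recovers it.  This example shows both
fits on one stimulated recording, then runs the paired cohort contrast.
"""

from aperiodic_ei import (PatientCohortConfig, PatientConfig, fit_aperiodic,
                          gen_patient_cohort, gen_patient_dataset,
                          interpolate_mains, morlet_power, run_dbs_contrast,
                          time_average_psd)

# one hemisphere: chi = 1.5 ON stimulation, with the artefact plateau
_, rec_on, _ = gen_patient_dataset(1.2, 1.5, seed=3,
                                   dbs_b={"plateau_level": 1.0})
tf = morlet_power(rec_on.data[0], rec_on.fs, 5, 90)
psd = interpolate_mains(time_average_psd(tf, norm_band=(5, 90)))
fit_low = fit_aperiodic(psd, (10, 50))
fit_high = fit_aperiodic(psd, (40, 90))
print(f"true chi ON stimulation = 1.5")
print(f"  10-50 Hz fit: chi = {fit_low.exponent:.2f} (R^2 = {fit_low.r2:.2f})")
print(f"  40-90 Hz fit: chi = {fit_high.exponent:.2f}  <- biased low by the "
      "plateau")

# paired cohort contrast (reduced size, strong imposed effect)
cohort = PatientCohortConfig.dbs(seed=9)
cohort.n_hemispheres = 8
cohort.delta_chi_sd = 0.08
pairs, _ = gen_patient_cohort(cohort)
report = run_dbs_contrast(pairs, PatientConfig(exp_fit_range=(10.0, 50.0),
                                               n_perms=5000, seed=9))
c = report.contrasts["exponent_on_minus_off"]
print(f"cohort exponent (ON - OFF stimulation), 10-50 Hz fit: "
      f"t = {c['t']:.2f}, p = {c['p']:.3g}, d = {c['cohens_d']:.2f}")
print("-> stimulation raises the exponent, consistent with suppressed STN "
      "firing; the lowered fit range keeps the artefact plateau out.")
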