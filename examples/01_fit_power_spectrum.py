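"""Parameterise a power spectrum into aperiodic and periodic components.

Builds a synthetic 1/f^1.5 LFP with a 20 Hz beta-band oscillation, estimates
its PSD, and fits the spectral model.  The printed exponent is the log-log
slope of the aperiodic background (the E/I marker); the peak parameters
describe the oscillation rising above that background.
"""

import numpy as np
from scipy import signal as sps

from aperiodic_ei import (Spectrum, add_oscillations, fit_model,
                          gen_powerlaw_noise, largest_peak_in_band)

FS = 2048.0

x = gen_powerlaw_noise(chi=1.5, fs=FS, duration_s=100.0, seed=1)
x = add_oscillations(x, FS, peaks=[(20.0, 0.5, 2.0)], seed=2)

freqs, pxx = sps.welch(x, fs=FS, nperseg=int(FS))
keep = (freqs >= 1) & (freqs <= 95)
spectrum = Spectrum(freqs[keep], pxx[keep])

model = fit_model(spectrum, f_range=(1, 90))
beta = largest_peak_in_band(model, (13, 35))

print(f"aperiodic exponent chi = {model.aperiodic.exponent:.3f}  (truth 1.5)")
print(f"model R^2 on log10 power = {model.r2:.4f}")
print(f"largest beta peak: cf = {beta.cf:.1f} Hz, height = {beta.pw:.2f} "
      f"log10 units, bandwidth = {beta.bw:.1f} Hz  (truth: 20 Hz, 0.5)")
print("-> the exponent describes how fast background power decays with "
      "frequency; the peak is the oscillation on top of it.")
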