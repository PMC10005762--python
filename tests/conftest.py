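"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own fitting/convolution
code paths: aperiodic parameters are checked against a coarse-to-fine grid
search minimising squared log-residuals, and wavelet responses against a
direct time-domain convolution built from the wavelet formula.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

from aperiodic_ei.spectral import Spectrum


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)


def welch_spectrum(x: np.ndarray, fs: float, f_max: float | None = None,
                   nperseg: int | None = None) -> Spectrum:
    """1 Hz-resolution Welch PSD as a Spectrum (DC dropped)."""
    f, p = sps.welch(x, fs=fs, nperseg=nperseg or int(fs))
    keep = f > 0
    if f_max is not None:
        keep &= f <= f_max
    return Spectrum(f[keep], p[keep])


def grid_search_aperiodic(freqs: np.ndarray, logp: np.ndarray,
                          mode: str = "fixed",
                          chi_range=(0.0, 4.0), knee_range=(0.0, 200.0),
                          n_refine: int = 3) -> tuple[float, float, float]:
    """Coarse-to-fine grid search for (offset, knee, chi) minimising the sum
    of squared log10 residuals.  Offset is profiled out analytically (it
    enters linearly)."""
    freqs = np.asarray(freqs, dtype=float)
    logp = np.asarray(logp, dtype=float)

    def sse(knee, chi):
        core = -np.log10(knee + freqs ** chi)
        b = np.mean(logp - core)
        return np.sum((logp - (b + core)) ** 2), b

    chi_lo, chi_hi = chi_range
    knee_lo, knee_hi = knee_range if mode == "knee" else (0.0, 0.0)
    best = None
    for _ in range(n_refine):
        chis = np.linspace(chi_lo, chi_hi, 41)
        knees = np.linspace(knee_lo, knee_hi, 41) if mode == "knee" else [0.0]
        for chi in chis:
            for knee in knees:
                s, b = sse(knee, chi)
                if best is None or s < best[0]:
                    best = (s, b, knee, chi)
        chi_step = (chi_hi - chi_lo) / 40
        chi_lo = max(chi_range[0], best[3] - 2 * chi_step)
        chi_hi = min(chi_range[1], best[3] + 2 * chi_step)
        if mode == "knee":
            knee_step = (knee_hi - knee_lo) / 40
            knee_lo = max(knee_range[0], best[2] - 2 * knee_step)
            knee_hi = min(knee_range[1], best[2] + 2 * knee_step)
    _, b, knee, chi = best
    return b, knee, chi


def direct_morlet_response(x: np.ndarray, fs: float, freq: float,
                           n_cycles: float = 50.0,
                           trunc_sd: float = 3.5) -> np.ndarray:
    """Brute-force complex Morlet convolution straight from the formula."""
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(trunc_sd * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    w = w / np.sqrt(np.sum(np.abs(w) ** 2) / fs)
    return np.convolve(x.astype(complex), w, mode="same") / fs


def oracle_single_peak_fit(freqs: np.ndarray, logp: np.ndarray,
                           seed: int = 0) -> dict:
    """Independent global fit of (offset, chi, cf, height, sigma) by seeded
    differential evolution on the squared log10 residuals.  Shares no code
    with the package's staged fitting algorithm."""
    from scipy.optimize import differential_evolution

    freqs = np.asarray(freqs, dtype=float)
    logp = np.asarray(logp, dtype=float)
    logf = np.log10(freqs)

    def sse(params):
        b, chi, cf, h, sig = params
        model = b - chi * logf + h * np.exp(-((freqs - cf) ** 2)
                                            / (2 * sig ** 2))
        return np.sum((logp - model) ** 2)

    bounds = [(-3, 3), (0, 4), (freqs[0], freqs[-1]), (0, 2), (1, 6)]
    res = differential_evolution(sse, bounds, seed=seed, tol=1e-10,
                                 maxiter=400, polish=True)
    b, chi, cf, h, sig = res.x
    return {"offset": b, "exponent": chi, "cf": cf, "height": h, "sigma": sig}
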