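"""Morlet wavelet decomposition and power-spectral-density handling.

The decomposition convention follows the analysis this package implements:
complex Morlet wavelets with a *fixed* number of cycles (default 50) on a
linear 1 Hz frequency grid, applied to the full-length time series before any
epoching so that epoch-level PSDs are not dominated by edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = [
    "BANDS",
    "TFPower",
    "Spectrum",
    "morlet_wavelet",
    "morlet_power",
    "epoch_psd",
    "time_average_psd",
    "average_psd",
    "interpolate_mains",
    "band_power",
]

#: Canonical frequency bands (Hz, inclusive bounds on the integer grid).
BANDS: dict[str, tuple[float, float]] = {
    "beta": (13, 35),
    "low_beta": (13, 20),
    "high_beta": (21, 35),
    "gamma": (35, 90),
    "low_gamma": (35, 50),
    "high_gamma": (51, 90),
}


@dataclass
class TFPower:
    """Time–frequency power from a continuous Morlet decomposition.

    Attributes
    ----------
    frequencies : 1-D array, Hz, strictly increasing linear grid.
    times : 1-D array, seconds, one entry per signal sample.
    power : (n_freqs, n_times) non-negative array, |wavelet coefficient|^2.
    n_cycles : number of wavelet cycles (constant across frequencies).
    """

    frequencies: np.ndarray
    times: np.ndarray
    power: np.ndarray
    n_cycles: float = 50.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.frequencies.size, self.times.size):
            raise ValueError("power must be (n_freqs, n_times)")
        steps = np.diff(self.frequencies)
        if self.frequencies.size > 1 and (
            np.any(steps <= 0) or not np.allclose(steps, steps[0])
        ):
            raise ValueError("frequency grid must be strictly increasing with constant step")

    @property
    def fs(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])


@dataclass
class Spectrum:
    """A power spectrum with provenance flags.

    ``power`` is in linear units unless ``flattened`` is set, in which case
    values are log10 residuals relative to an aperiodic model and may be
    negative.
    """

    frequencies: np.ndarray
    power: np.ndarray
    normalized_band: tuple[float, float] | None = None
    mains_interpolated: tuple[float, float] | None = None
    flattened: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if not self.flattened and np.any(self.power < 0):
            raise ValueError("linear power must be non-negative")

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.frequencies >= lo) & (self.frequencies <= hi)

    def slice(self, band: tuple[float, float]) -> "Spectrum":
        m = self.band_mask(band)
        if not np.any(m):
            raise ValueError(f"no grid points inside band {band}")
        return replace(self, frequencies=self.frequencies[m], power=self.power[m])


def morlet_wavelet(freq: float, fs: float, n_cycles: float = 50.0,
                   trunc_sd: float = 3.5) -> np.ndarray:
    """Unit-energy complex Morlet wavelet at ``freq`` Hz.

    w(t) = A * exp(i 2π f t) * exp(-t^2 / (2 σ_t^2)), σ_t = n_cycles / (2π f),
    truncated at ±``trunc_sd`` σ_t and normalised so that Σ|w|^2 Δt = 1.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(trunc_sd * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / fs)
    return w


def morlet_power(signal: np.ndarray, fs: float, f_lo: float = 1.0,
                 f_hi: float = 100.0, df: float = 1.0,
                 n_cycles: float = 50.0) -> TFPower:
    """Continuous Morlet decomposition of a single-channel signal.

    The convolution is applied to the full-length signal; epoch the returned
    power afterwards (see :func:`epoch_psd`).  Raises if the signal is shorter
    than the (truncated) wavelet at the lowest requested frequency.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if f_hi >= fs / 2:
        raise ValueError("f_hi must be below the Nyquist frequency")
    freqs = np.arange(f_lo, f_hi + df / 2, df, dtype=float)
    n = x.size
    longest = morlet_wavelet(freqs[0], fs, n_cycles).size
    if n < longest:
        raise ValueError(
            f"signal ({n} samples) shorter than the {freqs[0]:g} Hz wavelet "
            f"({longest} samples); decompose a longer segment before epoching"
        )
    nfft = next_fast_len(n + longest - 1)
    xf = fft(x, nfft)
    power = np.empty((freqs.size, n))
    dt = 1.0 / fs
    for i, f in enumerate(freqs):
        w = morlet_wavelet(f, fs, n_cycles)
        conv = ifft(xf * fft(w, nfft))
        start = (w.size - 1) // 2
        coef = conv[start:start + n] * dt
        power[i] = np.abs(coef) ** 2
    times = np.arange(n) / fs
    return TFPower(frequencies=freqs, times=times, power=power, n_cycles=n_cycles)


def _normalize(freqs: np.ndarray, psd: np.ndarray,
               norm_band: tuple[float, float] | None) -> np.ndarray:
    if norm_band is None:
        return psd
    lo, hi = norm_band
    m = (freqs >= lo) & (freqs <= hi)
    denom = psd[m].mean()
    if denom <= 0:
        raise ValueError("normalisation band has non-positive mean power")
    return psd / denom


def epoch_psd(tf: TFPower, epoch_len_s: float = 0.25,
              norm_band: tuple[float, float] | None = (1.0, 100.0)) -> list[Spectrum]:
    """Mean PSD per consecutive non-overlapping epoch, each normalised.

    Each epoch's PSD is the time-mean of wavelet power inside the epoch,
    divided by the scalar mean of that PSD over ``norm_band``.  The trailing
    partial epoch is discarded.
    """
    fs = tf.fs
    spe = int(round(epoch_len_s * fs))
    if spe < 1:
        raise ValueError("epoch length shorter than one sample")
    n_epochs = tf.power.shape[1] // spe
    out = []
    for e in range(n_epochs):
        psd = tf.power[:, e * spe:(e + 1) * spe].mean(axis=1)
        psd = _normalize(tf.frequencies, psd, norm_band)
        out.append(Spectrum(tf.frequencies.copy(), psd, normalized_band=norm_band))
    return out


def time_average_psd(tf: TFPower, norm_band: tuple[float, float] | None = None,
                     edge_exclude: bool = True) -> Spectrum:
    """Time-averaged PSD over the full window.

    With ``edge_exclude``, samples within two wavelet standard deviations of
    either end are dropped per frequency (capped at a quarter of the window
    per side) so boundary transients do not bias the average.
    """
    n = tf.times.size
    fs = tf.fs
    psd = np.empty(tf.frequencies.size)
    for i, f in enumerate(tf.frequencies):
        if edge_exclude:
            sigma_t = tf.n_cycles / (2.0 * np.pi * f)
            k = min(int(np.ceil(2.0 * sigma_t * fs)), n // 4)
        else:
            k = 0
        psd[i] = tf.power[i, k:n - k if k else n].mean()
    psd = _normalize(tf.frequencies, psd, norm_band)
    return Spectrum(tf.frequencies.copy(), psd, normalized_band=norm_band)


def average_psd(spectra: Sequence[Spectrum]) -> Spectrum:
    """Elementwise arithmetic mean of spectra on identical grids.

    Provenance flags are propagated only when shared by every input.
    """
    if len(spectra) == 0:
        raise ValueError("cannot average an empty list of spectra")
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != f0.shape or not np.array_equal(s.frequencies, f0):
            raise ValueError("frequency grid mismatch")
    mean = np.mean([s.power for s in spectra], axis=0)

    def shared(attr):
        vals = {getattr(s, attr) for s in spectra}
        return vals.pop() if len(vals) == 1 else None

    return Spectrum(
        f0.copy(), mean,
        normalized_band=shared("normalized_band"),
        mains_interpolated=shared("mains_interpolated"),
        flattened=all(s.flattened for s in spectra),
    )


def interpolate_mains(s: Spectrum, band: tuple[float, float] = (47.0, 53.0)) -> Spectrum:
    """Replace power inside ``band`` by linear interpolation across the gap.

    Used to excise mains interference (50 Hz and its skirts) before aperiodic
    fitting.  The anchors are the nearest grid points outside the band.
    """
    lo, hi = band
    f = s.frequencies
    if lo <= f[0] or hi >= f[-1]:
        raise ValueError("mains band must be interior to the spectrum")
    inside = (f >= lo) & (f <= hi)
    if not np.any(inside):
        return replace(s, mains_interpolated=band)
    left = np.where(f < lo)[0][-1]
    right = np.where(f > hi)[0][0]
    power = s.power.copy()
    power[inside] = np.interp(f[inside], [f[left], f[right]],
                              [power[left], power[right]])
    return replace(s, power=power, mains_interpolated=band)


def band_power(s: Spectrum, band: tuple[float, float],
               aperiodic=None) -> float:
    """Mean power inside ``band`` (inclusive bounds on the grid).

    With an aperiodic fit supplied the spectrum is flattened first (log10
    power minus the aperiodic model) and the mean of the log residuals is
    returned — the "1/f-corrected" band power.  Without one, the plain mean
    of linear power is returned.
    """
    sub = s.slice(band)
    if aperiodic is not None:
        from .specparam import flatten_spectrum  # noqa: PLC0415 — avoid cycle
        sub = flatten_spectrum(sub, aperiodic)
    return float(sub.power.mean())
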