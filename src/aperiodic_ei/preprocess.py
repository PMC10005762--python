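"""Filtering, resampling, local-average re-referencing and coherence QC.

All filters are applied forward–backward (zero phase) so that spike/LFP
timing relationships survive preprocessing; re-referencing subtracts the
mean of neighbouring contacts to suppress volume-conducted common-mode
signal, and wavelet magnitude-squared coherence against a reference channel
is the quality check that the suppression worked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import Recording
from .spectral import morlet_wavelet

logger = logging.getLogger(__name__)

__all__ = [
    "CoherenceSpectrum",
    "butterworth_filter",
    "resample_signal",
    "local_average_reference",
    "neighbor_channels",
    "wavelet_coherence",
]


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence per frequency, each value in [0, 1]."""

    frequencies: np.ndarray
    msc: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.msc = np.asarray(self.msc, dtype=float)
        if np.any(self.msc < -1e-9) or np.any(self.msc > 1 + 1e-9):
            raise ValueError("magnitude-squared coherence must lie in [0, 1]")
        self.msc = np.clip(self.msc, 0.0, 1.0)


def butterworth_filter(rec: Recording, kind: str, cutoff_hz: float,
                       order: int = 3) -> Recording:
    """Zero-phase Butterworth filter (forward–backward) on every channel.

    ``kind`` is "lowpass" or "highpass".  The effective magnitude response is
    the squared single-pass response; there is no group delay.
    """
    if kind not in ("lowpass", "highpass"):
        raise ValueError("kind must be 'lowpass' or 'highpass'")
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, cutoff_hz, btype=kind, fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def resample_signal(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling with built-in anti-aliasing.

    Handles non-integer ratios (e.g. 17.9 kHz -> 2048 Hz) via a rational
    approximation of the rate change; duration is preserved to within one
    sample period.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == rec.fs:
        return replace(rec, data=rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator,
                         axis=1, window=("kaiser", 14.0))
    actual_fs = rec.fs * frac.numerator / frac.denominator
    return replace(rec, data=data, fs=actual_fs)


def neighbor_channels(rec: Recording, target_channel: str,
                      n_neighbors: int = 6) -> list[str]:
    """Pick re-referencing neighbours for a target contact.

    With geometry: the nearest contacts on the same array by position
    (ideally half above, half below); at array edges the nearest
    ``n_neighbors`` along the array are used, with a logged warning.
    Without geometry: adjacency in channel order.
    """
    target_channel = str(target_channel)
    if rec.geometry is not None:
        geo = rec.geometry
        arr = geo[target_channel]["array"]
        pos = geo[target_channel]["position_um"]
        same = [c for c in rec.channel_ids
                if c != target_channel and geo[c]["array"] == arr]
        same.sort(key=lambda c: abs(geo[c]["position_um"] - pos))
        chosen = same[:n_neighbors]
        above = sum(geo[c]["position_um"] > pos for c in chosen)
        if abs(2 * above - len(chosen)) > 1:
            logger.warning("channel %s is near an array edge; using the "
                           "nearest %d contacts along the array",
                           target_channel, n_neighbors)
    else:
        idx = rec.channel_ids.index(target_channel)
        order = sorted(range(rec.n_channels),
                       key=lambda j: (abs(j - idx), j))
        chosen = [rec.channel_ids[j] for j in order if j != idx][:n_neighbors]
    if len(chosen) < n_neighbors:
        raise ValueError(
            f"only {len(chosen)} neighbours available for {target_channel}; "
            f"{n_neighbors} requested"
        )
    return chosen


def local_average_reference(rec: Recording, target_channel: str,
                            neighbor_ids: list[str] | None = None) -> np.ndarray:
    """Target signal minus the mean of its neighbouring contacts."""
    target_channel = str(target_channel)
    if neighbor_ids is None:
        neighbor_ids = neighbor_channels(rec, target_channel)
    neighbor_ids = [str(c) for c in neighbor_ids]
    if target_channel in neighbor_ids:
        raise ValueError("target channel cannot be its own neighbour")
    missing = [c for c in neighbor_ids if c not in rec.channel_ids]
    if missing:
        raise ValueError(f"neighbour channels not in recording: {missing}")
    ref = np.mean([rec.channel(c) for c in neighbor_ids], axis=0)
    return rec.channel(target_channel) - ref


def wavelet_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                      freqs: np.ndarray, n_cycles: float = 50.0,
                      n_windows: int = 8) -> CoherenceSpectrum:
    """Wavelet magnitude-squared coherence, time-averaged over windows.

    msc(f) = |<Wx conj(Wy)>|^2 / (<|Wx|^2> <|Wy|^2>), where <.> averages the
    per-window means; at least ``n_windows`` >= 8 windows are required for a
    meaningful estimate.  Uses the same Morlet family as the spectral module.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D signals")
    if not np.any(x) and not np.any(y):
        raise ValueError("coherence of identical zero signals is undefined")
    if n_windows < 8:
        raise ValueError("need at least 8 windows for a coherence estimate")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("freqs must lie strictly inside (0, fs/2)")
    n = x.size
    win = n // n_windows
    if win < 2:
        raise ValueError("signals too short for the requested window count")
    msc = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        w = morlet_wavelet(f, fs, n_cycles)
        wx = sps.fftconvolve(x.astype(complex), w, mode="same") / fs
        wy = sps.fftconvolve(y.astype(complex), w, mode="same") / fs
        sxy = np.empty(n_windows, dtype=complex)
        sxx = np.empty(n_windows)
        syy = np.empty(n_windows)
        for k in range(n_windows):
            sl = slice(k * win, (k + 1) * win)
            sxy[k] = np.mean(wx[sl] * np.conj(wy[sl]))
            sxx[k] = np.mean(np.abs(wx[sl]) ** 2)
            syy[k] = np.mean(np.abs(wy[sl]) ** 2)
        denom = sxx.mean() * syy.mean()
        msc[i] = np.abs(sxy.mean()) ** 2 / denom if denom > 0 else 0.0
    return CoherenceSpectrum(frequencies=freqs, msc=msc)
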