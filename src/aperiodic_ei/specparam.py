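"""Aperiodic + periodic power-spectrum parameterisation.

Decomposes a power spectrum into an aperiodic background

    log10 P(f) = b - log10(k + f^chi)          (knee mode; fixed mode: k = 0)

plus a sum of Gaussian peaks in log10 space.  ``chi`` is the aperiodic
exponent: the magnitude of the log-log slope of the non-oscillatory
background, the quantity this package treats as a marker of the
excitation/inhibition balance of the recorded population.

The fitting procedure is a from-scratch implementation of the widely used
periodic/aperiodic parameterisation algorithm (1.0.0 semantics): a robust
aperiodic fit that down-weights points sitting on oscillatory peaks, greedy
Gaussian extraction from the flattened spectrum, a joint Gaussian refit, and
a final aperiodic refit on the peak-removed spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .spectral import Spectrum

__all__ = [
    "AperiodicFit",
    "PeakParams",
    "SpecparamSettings",
    "SpectralModel",
    "aperiodic_model",
    "gaussian",
    "fit_aperiodic",
    "fit_model",
    "flatten_spectrum",
    "largest_peak_in_band",
]

# Internal algorithm constants (reference-implementation semantics).
_AP_PERCENTILE_THRESH = 2.5   # percentile of clipped residuals kept in robust refit
_CF_BOUND_STDS = 2.0          # joint-fit bound on each centre frequency, in guess SDs
_OVERLAP_THRESH = 0.75        # peaks closer than this (in summed SDs) are merged
_MAX_PEAKS_CAP = 50           # guard for "infinite" max peaks
_MIN_PEAK_FLOOR = 1e-6        # numerical floor: residuals below this are noise


@dataclass(frozen=True)
class AperiodicFit:
    """Aperiodic component: offset ``b`` (log10 power), optional knee ``k``,
    exponent ``chi``, the frequency range fitted, and R² on log10 power."""

    mode: str                     # "fixed" | "knee"
    offset: float
    exponent: float
    knee: float | None
    fit_range: tuple[float, float]
    r2: float

    def __post_init__(self):
        if self.mode not in ("fixed", "knee"):
            raise ValueError("mode must be 'fixed' or 'knee'")
        if self.mode == "fixed" and self.knee is not None:
            raise ValueError("fixed mode has no knee parameter")
        if not math.isfinite(self.exponent):
            raise ValueError("exponent must be finite")

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        """Model curve in log10 power on ``freqs``."""
        k = 0.0 if self.knee is None else self.knee
        return aperiodic_model(np.asarray(freqs, dtype=float),
                               self.offset, k, self.exponent)


@dataclass(frozen=True)
class PeakParams:
    """One oscillatory peak: centre frequency (Hz), power (log10 units above
    the aperiodic background at the centre), bandwidth (Hz, two Gaussian SDs)."""

    cf: float
    pw: float
    bw: float


@dataclass(frozen=True)
class SpecparamSettings:
    peak_width_limits: tuple[float, float] = (2.0, 12.0)
    max_n_peaks: int | None = None          # None = unbounded (guarded cap)
    min_peak_height: float = 0.0
    peak_threshold: float = 2.0             # in SDs of the flattened spectrum
    aperiodic_mode: str = "fixed"

    @property
    def gauss_std_limits(self) -> tuple[float, float]:
        lo, hi = self.peak_width_limits
        return lo / 2.0, hi / 2.0

    @property
    def peak_cap(self) -> int:
        return self.max_n_peaks if self.max_n_peaks is not None else _MAX_PEAKS_CAP


@dataclass
class SpectralModel:
    aperiodic: AperiodicFit
    peaks: list[PeakParams]
    settings: SpecparamSettings
    r2: float
    fit_range: tuple[float, float]
    non_converged: bool = False

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        """Full model (aperiodic + peaks) in log10 power."""
        freqs = np.asarray(freqs, dtype=float)
        model = self.aperiodic.evaluate(freqs)
        for p in self.peaks:
            model += gaussian(freqs, p.cf, p.pw, p.bw / 2.0)
        return model


def aperiodic_model(freqs: np.ndarray, offset: float, knee: float,
                    exponent: float) -> np.ndarray:
    return offset - np.log10(knee + freqs ** exponent)


def gaussian(freqs: np.ndarray, cf: float, height: float, std: float) -> np.ndarray:
    return height * np.exp(-((freqs - cf) ** 2) / (2.0 * std ** 2))


def _prepare(s: Spectrum, f_range: tuple[float, float]):
    lo, hi = f_range
    if lo >= hi:
        raise ValueError("fit range lower bound must be below upper bound")
    mask = s.band_mask(f_range)
    freqs = s.frequencies[mask]
    if freqs.size < 3:
        raise ValueError("fit range contains fewer than 3 grid points")
    power = s.power[mask]
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive on the fit range")
    return freqs, np.log10(power)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-20 else 0.0
    return 1.0 - ss_res / ss_tot


def _simple_ap_fit(freqs, logp, mode, guess=None):
    slope = (logp[-1] - logp[0]) / (np.log10(freqs[-1]) - np.log10(freqs[0]))
    exp_guess = abs(slope)
    if mode == "fixed":
        def model(f, b, chi):
            return aperiodic_model(f, b, 0.0, chi)
        if guess is not None:
            p0 = [guess[0], guess[2]]
        else:
            p0 = [logp[0] + exp_guess * np.log10(freqs[0]), exp_guess]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, freqs, logp, p0=p0, maxfev=5000,
                                ftol=1e-12, xtol=1e-12)
        return np.array([popt[0], 0.0, popt[1]])
    # knee mode: the SSE surface has local minima in k, so try a ladder of
    # knee guesses and keep the best.
    def model(f, b, k, chi):
        return aperiodic_model(f, b, k, chi)
    best, best_sse = None, np.inf
    knee_guesses = [0.0, 1.0, 10.0, 100.0, 1000.0] if guess is None else [guess[1]]
    for kg in knee_guesses:
        p0 = ([logp[0], kg, exp_guess] if guess is None
              else [guess[0], kg, guess[2]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(model, freqs, logp, p0=p0,
                                    bounds=([-np.inf, 0.0, -np.inf],
                                            [np.inf, np.inf, np.inf]),
                                    maxfev=5000, ftol=1e-12, xtol=1e-12)
        except RuntimeError:
            continue
        sse = float(np.sum((model(freqs, *popt) - logp) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError("aperiodic knee fit did not converge")
    return np.asarray(best)


def _robust_ap_fit(freqs, logp, mode):
    params = _simple_ap_fit(freqs, logp, mode)
    resid = logp - aperiodic_model(freqs, *params)
    flat = np.where(resid < 0, 0.0, resid)
    thresh = np.percentile(flat, _AP_PERCENTILE_THRESH)
    keep = flat <= thresh + 1e-12
    if keep.sum() >= 3:
        params = _simple_ap_fit(freqs[keep], logp[keep], mode, guess=params)
    return params


def fit_aperiodic(s: Spectrum, f_range: tuple[float, float],
                  mode: str = "fixed") -> AperiodicFit:
    """Robust aperiodic fit on log10 power over ``f_range``.

    An initial least-squares fit is refined on the subset of points whose
    positive residual falls below a low percentile, which discounts grid
    points sitting on oscillatory peaks.
    """
    if mode not in ("fixed", "knee"):
        raise ValueError("mode must be 'fixed' or 'knee'")
    freqs, logp = _prepare(s, f_range)
    params = _robust_ap_fit(freqs, logp, mode)
    r2 = _r_squared(logp, aperiodic_model(freqs, *params))
    return AperiodicFit(mode=mode, offset=float(params[0]),
                        knee=float(params[1]) if mode == "knee" else None,
                        exponent=float(params[2]),
                        fit_range=(float(f_range[0]), float(f_range[1])), r2=r2)


def flatten_spectrum(s: Spectrum, ap: AperiodicFit) -> Spectrum:
    """log10 power minus the aperiodic model: the flattened spectrum."""
    lo, hi = ap.fit_range
    if s.frequencies[0] < lo - 1e-9 or s.frequencies[-1] > hi + 1e-9:
        raise ValueError("spectrum grid extends outside the aperiodic fit range")
    if s.flattened:
        raise ValueError("spectrum is already flattened")
    if np.any(s.power <= 0):
        raise ValueError("power must be strictly positive to flatten")
    flat = np.log10(s.power) - ap.evaluate(s.frequencies)
    out = Spectrum(s.frequencies.copy(), flat, normalized_band=s.normalized_band,
                   mains_interpolated=s.mains_interpolated, flattened=True)
    return out


def _guess_std(freqs, flat, idx, height, limits):
    """Half-height width on the shorter side -> Gaussian SD, clipped."""
    half = height / 2.0
    le = ri = None
    for j in range(idx - 1, -1, -1):
        if flat[j] <= half:
            le = idx - j
            break
    for j in range(idx + 1, flat.size):
        if flat[j] <= half:
            ri = j - idx
            break
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    sides = [sd for sd in (le, ri) if sd is not None]
    if sides:
        fwhm = 2.0 * min(sides) * df
        std = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    else:
        std = np.mean(limits)
    return float(np.clip(std, *limits))


def _multi_gaussian(freqs, *params):
    total = np.zeros_like(freqs)
    for i in range(0, len(params), 3):
        total += gaussian(freqs, params[i], params[i + 1], params[i + 2])
    return total


def _drop_overlaps(guesses):
    """Where two Gaussians overlap substantially, keep the taller one."""
    guesses = sorted(guesses, key=lambda g: g[0])
    changed = True
    while changed and len(guesses) > 1:
        changed = False
        for i in range(len(guesses) - 1):
            (cf1, h1, s1), (cf2, h2, s2) = guesses[i], guesses[i + 1]
            if cf1 + _OVERLAP_THRESH * s1 > cf2 - _OVERLAP_THRESH * s2:
                del guesses[i if h1 < h2 else i + 1]
                changed = True
                break
    return guesses


def fit_model(s: Spectrum, f_range: tuple[float, float],
              settings: SpecparamSettings | None = None) -> SpectralModel:
    """Full periodic + aperiodic model fit.

    Steps: robust aperiodic fit; greedy Gaussian extraction from the
    flattened spectrum (accepted while the running maximum exceeds both the
    relative threshold, in SDs of the flattened spectrum, and the absolute
    minimum height); joint Gaussian refit; final aperiodic refit on the
    peak-removed spectrum.
    """
    settings = settings or SpecparamSettings()
    freqs, logp = _prepare(s, f_range)
    mode = settings.aperiodic_mode
    std_lo, std_hi = settings.gauss_std_limits

    ap_params = _robust_ap_fit(freqs, logp, mode)
    flat = logp - aperiodic_model(freqs, *ap_params)

    # greedy peak extraction
    guesses = []
    work = flat.copy()
    while len(guesses) < settings.peak_cap:
        idx = int(np.argmax(work))
        height = work[idx]
        if height <= settings.peak_threshold * np.std(work):
            break
        if not height > max(settings.min_peak_height, _MIN_PEAK_FLOOR):
            break
        std = _guess_std(freqs, work, idx, height, (std_lo, std_hi))
        guesses.append((float(freqs[idx]), float(height), std))
        work = work - gaussian(freqs, freqs[idx], height, std)
    guesses = _drop_overlaps(guesses)

    non_converged = False
    peaks: list[PeakParams] = []
    if guesses:
        p0, lo_b, hi_b = [], [], []
        for cf, h, std in guesses:
            p0 += [cf, h, std]
            lo_b += [max(freqs[0], cf - _CF_BOUND_STDS * std), 0.0, std_lo]
            hi_b += [min(freqs[-1], cf + _CF_BOUND_STDS * std), np.inf, std_hi]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_multi_gaussian, freqs, flat, p0=p0,
                                    bounds=(lo_b, hi_b), maxfev=8000)
        except RuntimeError:
            popt = np.asarray(p0)
            non_converged = True
        for i in range(0, len(popt), 3):
            peaks.append(PeakParams(cf=float(popt[i]), pw=float(popt[i + 1]),
                                    bw=float(2.0 * popt[i + 2])))
        peaks.sort(key=lambda p: p.cf)

    # final aperiodic refit on the peak-removed spectrum
    peak_curve = np.zeros_like(freqs)
    for p in peaks:
        peak_curve += gaussian(freqs, p.cf, p.pw, p.bw / 2.0)
    ap_params = _simple_ap_fit(freqs, logp - peak_curve, mode, guess=ap_params)

    aperiodic = AperiodicFit(
        mode=mode, offset=float(ap_params[0]),
        knee=float(ap_params[1]) if mode == "knee" else None,
        exponent=float(ap_params[2]),
        fit_range=(float(f_range[0]), float(f_range[1])),
        r2=_r_squared(logp, aperiodic_model(freqs, *ap_params)),
    )
    model_curve = aperiodic.evaluate(freqs) + peak_curve
    r2 = _r_squared(logp, model_curve)
    return SpectralModel(aperiodic=aperiodic, peaks=peaks, settings=settings,
                         r2=r2, fit_range=aperiodic.fit_range,
                         non_converged=non_converged)


def largest_peak_in_band(model: SpectralModel,
                         band: tuple[float, float]) -> PeakParams | None:
    """Highest-power peak with centre frequency inside ``band`` (inclusive).

    Ties in power break toward the lower centre frequency.  Returns None
    when no peak falls in the band.
    """
    lo, hi = band
    in_band = [p for p in model.peaks if lo <= p.cf <= hi]
    if not in_band:
        return None
    return max(in_band, key=lambda p: (p.pw, -p.cf))
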