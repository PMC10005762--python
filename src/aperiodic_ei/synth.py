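"""Synthetic LFP and spike-train generators with known ground truth.

Two dataset families are emulated:

* a rodent-style dataset — STN LFPs during cortical slow-wave activity
  (~1 Hz), with a 1/f^chi background whose exponent switches between a
  "high STN spiking" value (chi_high, excitation-dominated) and a "low STN
  spiking" value (chi_low, inhibition-dominated) in time with the slow
  oscillation, plus STN/GPe spike trains phase-locked to it in anti-phase;

* a patient-style dataset — per-hemisphere 60 s ON/OFF condition pairs with
  a condition-dependent exponent, a beta-band oscillatory peak, 50 Hz mains,
  and (for stimulation) 65/130 Hz artefact tones over a white-noise floor
  that produces the characteristic spectral plateau above ~50 Hz.

All generators are deterministic given a seed and return a ground-truth
dictionary alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Recording, SpikeTrain

__all__ = [
    "SynthConfig",
    "PatientCohortConfig",
    "gen_powerlaw_noise",
    "add_oscillations",
    "gen_phase_locked_spikes",
    "gen_rodent_dataset",
    "gen_patient_dataset",
    "gen_patient_cohort",
]

@dataclass
class SynthConfig:
    """Ground-truth parameters for one synthetic session.

    The defaults are the rodent study conditions: 8 animals with ~100 s of
    slow-wave activity each, 28 STN LFP channels in total (4/3 alternating
    per animal) and 20 isolated STN units (3/2 alternating), aperiodic
    exponent 1.0 during high STN firing vs 1.3 during low firing.
    """

    fs: float = 2048.0
    duration_s: float = 100.0
    n_animals: int = 8
    lfp_per_animal: tuple[int, ...] = (4, 3)     # cycled across animals
    units_per_animal: tuple[int, ...] = (3, 2)
    chi_high: float = 1.0          # aperiodic exponent, high STN firing state
    chi_low: float = 1.3           # aperiodic exponent, low STN firing state
    slow_freq: float = 1.0         # Hz, cortical slow oscillation
    slow_amp: float = 1.5          # in units of background SD
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    # per population: (baseline rate sp/s, modulation depth in [0, 1])
    stn_rate: tuple[float, float] = (12.0, 0.9)
    gpe_rate: tuple[float, float] = (24.0, 0.9)
    antiphase: bool = True
    mains_amp: float = 0.0         # 50 Hz sinusoid amplitude (background-SD units)
    dbs: dict | None = None        # {"freq","harmonic_amps","plateau_level"}
    seed: int = 0

    def __post_init__(self):
        if self.chi_high < 0 or self.chi_low < 0:
            raise ValueError("exponents must be non-negative")
        for _, depth in (self.stn_rate, self.gpe_rate):
            if not 0 <= depth <= 1:
                raise ValueError("modulation depth must lie in [0, 1]")
        top = max([100.0] + [cf for cf, *_ in self.peaks])
        if self.fs <= 2 * top:
            raise ValueError("fs must exceed twice the highest frequency of interest")


def gen_powerlaw_noise(chi: float, fs: float, duration_s: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Gaussian 1/f^chi noise, unit variance, deterministic per seed.

    White noise is shaped in the frequency domain by multiplying FFT
    amplitudes with f^(-chi/2) (DC set to zero) and inverse-transformed.
    """
    if chi < 0:
        raise ValueError("chi must be non-negative")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("duration * fs must be at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-chi / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _shaped_noise(psd_shape: np.ndarray, n: int, rng: np.random.Generator,
                  exact_amplitude: bool = False) -> np.ndarray:
    """Gaussian noise whose PSD is proportional to ``psd_shape`` (rfft grid).

    With ``exact_amplitude`` the spectral amplitudes are set exactly (random
    phases only), removing realisation-to-realisation power fluctuations —
    useful when a component's spectral height is itself the ground truth.
    """
    if exact_amplitude:
        phases = np.exp(2j * np.pi * rng.uniform(size=psd_shape.size))
        spec = np.sqrt(n * psd_shape) * phases
        spec[0] = 0.0
        if n % 2 == 0:
            spec[-1] = np.abs(spec[-1])
    else:
        spec = np.fft.rfft(rng.standard_normal(n)) * np.sqrt(psd_shape)
    return np.fft.irfft(spec, n=n)


def _background_psd_level(signal: np.ndarray, fs: float, cf: float,
                          halfwidth: float = 6.0) -> float:
    """Background PSD at ``cf`` estimated from the two flanking bands just
    outside the peak, interpolated in log-log space to first order in the
    local spectral slope."""
    freqs, pxx = sps.welch(signal, fs=fs, nperseg=int(4 * fs))
    lo = (freqs >= cf - 2 * halfwidth) & (freqs < cf - halfwidth) & (freqs > 0)
    hi = (freqs > cf + halfwidth) & (freqs <= cf + 2 * halfwidth)
    if not (lo.any() and hi.any()):
        flank = ((np.abs(freqs - cf) > halfwidth) &
                 (np.abs(freqs - cf) <= 2 * halfwidth) & (freqs > 0))
        return float(np.median(pxx[flank]))
    f_lo, p_lo = np.median(freqs[lo]), np.median(pxx[lo])
    f_hi, p_hi = np.median(freqs[hi]), np.median(pxx[hi])
    slope = (np.log(p_hi) - np.log(p_lo)) / (np.log(f_hi) - np.log(f_lo))
    return float(np.exp(np.log(p_lo) + slope * (np.log(cf) - np.log(f_lo))))


def add_oscillations(signal: np.ndarray, fs: float,
                     peaks: list[tuple[float, float, float]] | None = None,
                     slow_freq: float | None = None, slow_amp: float = 0.0,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add a slow sinusoid and narrowband oscillatory components.

    Each peak is (cf, height_log10, sigma_hz): an independent noise component
    is FFT-shaped with a Gaussian spectral profile centred at ``cf`` and
    scaled against the signal's own background PSD so the summed spectrum
    shows about ``height_log10`` (log10 units) above the background at cf —
    the height the spectral parameterisation should recover.
    """
    x = np.asarray(signal, dtype=float).copy()
    n = x.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for cf, height, sigma in peaks or []:
        if cf >= fs / 2:
            raise ValueError("peak centre frequency must be below Nyquist")
        if height <= 0:
            continue
        bg = _background_psd_level(x, fs, cf, halfwidth=max(3 * sigma, 4.0))
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        gain = 10.0 ** (height * np.exp(-((freqs - cf) ** 2) / (2 * sigma ** 2)))
        # welch returns one-sided density; _shaped_noise emits density
        # psd_shape * 2/fs, hence the fs/2 factor
        psd_shape = bg * (gain - 1.0) * fs / 2.0
        x += _shaped_noise(np.maximum(psd_shape, 0.0), n, rng,
                           exact_amplitude=True)
    if slow_freq is not None and slow_amp != 0.0:
        t = np.arange(n) / fs
        x += slow_amp * np.cos(2 * np.pi * slow_freq * t)
    return x


def gen_phase_locked_spikes(slow_freq: float, duration_s: float,
                            rate_params: tuple[float, float],
                            phase_offset: float = 0.0,
                            seed: int | np.random.Generator = 0,
                            unit_id: str = "u0",
                            refractory_s: float = 0.0) -> SpikeTrain:
    """Inhomogeneous Poisson spike train phase-locked to the slow oscillation.

    Rate lambda(t) = r0 (1 + m cos(2 pi slow_freq t - phase_offset)),
    realised by thinning a homogeneous train at the peak rate.  A positive
    ``refractory_s`` imposes an absolute refractory period (spikes arriving
    sooner after the previous accepted spike are dropped), as in well
    isolated single units.
    """
    r0, m = rate_params
    if r0 <= 0:
        raise ValueError("baseline rate must be positive")
    if not 0 <= m <= 1:
        raise ValueError("modulation depth must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam_max = r0 * (1 + m)
    n_cand = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0, duration_s, size=n_cand))
    lam = r0 * (1 + m * np.cos(2 * np.pi * slow_freq * cand - phase_offset))
    keep = rng.uniform(0, lam_max, size=n_cand) < lam
    times = np.unique(cand[keep])
    if refractory_s > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory_s:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain(unit_id=unit_id, times_s=times)


def _state_weight(t: np.ndarray, slow_freq: float, ramp_s: float = 0.025) -> np.ndarray:
    """Crossfade weight for the high-firing state: ~1 on the active phase of
    the slow oscillation, ~0 on the inactive phase, with cosine ramps."""
    phase = np.cos(2 * np.pi * slow_freq * t)
    # distance (s) from the zero crossing, mapped through a cosine ramp
    half_period = 0.5 / slow_freq
    frac = np.arccos(np.clip(phase, -1, 1)) / np.pi       # 0 at peak, 1 at trough
    dist = np.abs(frac - 0.5) * half_period               # s from nearest crossing
    ramp = np.clip(dist / ramp_s, 0.0, 1.0)
    smooth = 0.5 - 0.5 * np.cos(np.pi * ramp)             # 0 -> 1 over the ramp
    return np.where(frac < 0.5, 0.5 + 0.5 * smooth, 0.5 - 0.5 * smooth)


def gen_rodent_dataset(cfg: SynthConfig) -> tuple[list[Recording],
                                                  list[list[SpikeTrain]], dict]:
    """Rodent-style multi-animal dataset with state-dependent exponent.

    Per animal: several single-channel STN LFPs built by crossfading two
    power-law backgrounds (chi_high on the active phase of the slow
    oscillation, when STN units fire most; chi_low on the inactive phase),
    plus the slow oscillation itself and any configured oscillatory peaks;
    STN unit spike trains phase-locked to the active phase and GPe trains in
    anti-phase.  Channels are emitted already re-referenced (single
    channel).  Returns (recordings, spike trains per animal, ground truth).
    """
    if cfg.chi_high > cfg.chi_low:
        raise ValueError("expected chi_high <= chi_low (steeper spectra in the "
                         "low-firing, inhibition-dominated state)")
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    w = _state_weight(t, cfg.slow_freq)
    recordings, all_trains = [], []
    truth: dict = {"chi_high": cfg.chi_high, "chi_low": cfg.chi_low,
                   "slow_freq": cfg.slow_freq, "animals": []}
    for a in range(cfg.n_animals):
        n_lfp = cfg.lfp_per_animal[a % len(cfg.lfp_per_animal)]
        n_units = cfg.units_per_animal[a % len(cfg.units_per_animal)]
        chans = []
        for c in range(n_lfp):
            hi = gen_powerlaw_noise(cfg.chi_high, cfg.fs, cfg.duration_s, rng)
            lo = gen_powerlaw_noise(cfg.chi_low, cfg.fs, cfg.duration_s, rng)
            x = w * hi + (1 - w) * lo
            x = add_oscillations(x, cfg.fs, cfg.peaks, cfg.slow_freq,
                                 cfg.slow_amp, rng)
            if cfg.mains_amp:
                x = x + cfg.mains_amp * np.sin(2 * np.pi * 50.0 * t)
            chans.append(x)
        rec = Recording(data=np.stack(chans), fs=cfg.fs,
                        channel_ids=[f"a{a}_lfp{c}" for c in range(n_lfp)])
        trains = []
        for u in range(n_units):
            trains.append(gen_phase_locked_spikes(
                cfg.slow_freq, cfg.duration_s, cfg.stn_rate, phase_offset=0.0,
                seed=rng, unit_id=f"a{a}_stn{u}", refractory_s=0.003))
        gpe_offset = np.pi if cfg.antiphase else 0.0
        trains.append(gen_phase_locked_spikes(
            cfg.slow_freq, cfg.duration_s, cfg.gpe_rate, phase_offset=gpe_offset,
            seed=rng, unit_id=f"a{a}_gpe0", refractory_s=0.003))
        recordings.append(rec)
        all_trains.append(trains)
        truth["animals"].append({"animal": a, "n_lfp": n_lfp, "n_units": n_units})
    return recordings, all_trains, truth


@dataclass
class PatientCohortConfig:
    """Study conditions for a patient-style paired cohort.

    Effect sizes follow the reported group statistics: the medication
    contrast uses a mean exponent increase of 0.15 ON with SD 0.25 across
    hemispheres (Cohen's d 0.6, n = 30); the stimulation contrast uses
    0.30 with SD 0.244 (d 1.23, n = 26) plus a >50 Hz artefact plateau ON.
    """

    condition: str = "meds"        # "meds" | "dbs"
    n_hemispheres: int = 30
    fs: float = 2048.0
    duration_s: float = 60.0
    chi_off_mean: float = 1.2
    chi_off_sd: float = 0.25
    delta_chi_mean: float = 0.15
    delta_chi_sd: float = 0.25
    beta_cf_range: tuple[float, float] = (15.0, 30.0)
    beta_height_off: tuple[float, float] = (0.35, 0.12)   # mean, sd (log10)
    delta_beta_mean: float = -0.10
    delta_beta_sd: float = 0.26
    beta_sigma_range: tuple[float, float] = (1.5, 3.0)
    mains_amp: float = 1.0
    dbs_plateau: bool = False
    dbs_harmonics: tuple[float, ...] = (65.0, 130.0)
    seed: int = 0

    @classmethod
    def meds(cls, seed: int = 0) -> "PatientCohortConfig":
        return cls(condition="meds", n_hemispheres=30, delta_chi_mean=0.15,
                   delta_chi_sd=0.25, delta_beta_mean=-0.10, delta_beta_sd=0.26,
                   seed=seed)

    @classmethod
    def dbs(cls, seed: int = 0) -> "PatientCohortConfig":
        return cls(condition="dbs", n_hemispheres=26, delta_chi_mean=0.30,
                   delta_chi_sd=0.244, delta_beta_mean=-0.15, delta_beta_sd=0.26,
                   dbs_plateau=True, seed=seed)


def _patient_signal(chi: float, beta: tuple[float, float, float] | None,
                    fs: float, duration_s: float, mains_amp: float,
                    dbs: dict | None, rng: np.random.Generator) -> np.ndarray:
    x = gen_powerlaw_noise(chi, fs, duration_s, rng)
    peaks = [beta] if beta and beta[1] > 0 else []
    x = add_oscillations(x, fs, peaks, seed=rng)
    n = x.size
    t = np.arange(n) / fs
    if mains_amp:
        x = x + mains_amp * np.sin(2 * np.pi * 50.0 * t)
    if dbs is not None:
        # Stimulation artefact floor: white noise pinned to the background
        # level near 50 Hz, highpassed so its energy sits above ~50 Hz.
        # This flattens the spectrum >50 Hz (the ON-stimulation plateau)
        # while leaving the 10-50 Hz range dominated by the 1/f background.
        bg50 = _background_psd_level(x, fs, 50.0, halfwidth=5.0)
        floor = dbs.get("plateau_level", 1.0) * bg50
        white = np.sqrt(floor * fs / 2.0) * rng.standard_normal(n)
        cutoff = dbs.get("plateau_onset_hz", 52.0)
        sos = sps.butter(6, cutoff, btype="highpass", fs=fs, output="sos")
        x = x + sps.sosfiltfilt(sos, white)
        for f_art, amp in zip(dbs.get("freqs", (65.0, 130.0)),
                              dbs.get("harmonic_amps", (0.5, 1.0))):
            if f_art < fs / 2:
                x = x + amp * np.sin(2 * np.pi * f_art * t + rng.uniform(0, 2 * np.pi))
    return x


def gen_patient_dataset(chi_a: float, chi_b: float, fs: float = 2048.0,
                        duration_s: float = 60.0,
                        beta_a: tuple[float, float, float] | None = None,
                        beta_b: tuple[float, float, float] | None = None,
                        mains_amp: float = 1.0, dbs_b: dict | None = None,
                        seed: int = 0) -> tuple[Recording, Recording, dict]:
    """One hemisphere's paired recordings for conditions A (e.g. OFF) and B
    (ON medication or ON stimulation)."""
    rng = np.random.default_rng(seed)
    xa = _patient_signal(chi_a, beta_a, fs, duration_s, mains_amp, None, rng)
    xb = _patient_signal(chi_b, beta_b, fs, duration_s, mains_amp, dbs_b, rng)
    rec_a = Recording(data=xa[None, :], fs=fs, channel_ids=["lfp"])
    rec_b = Recording(data=xb[None, :], fs=fs, channel_ids=["lfp"])
    truth = {"chi_a": chi_a, "chi_b": chi_b, "beta_a": beta_a, "beta_b": beta_b,
             "mains_amp": mains_amp, "dbs_b": dbs_b is not None, "seed": seed}
    return rec_a, rec_b, truth


def gen_patient_cohort(cfg: PatientCohortConfig) -> tuple[
        list[tuple[Recording, Recording]], dict]:
    """Paired OFF/ON cohort with hemisphere-level variability.

    Returns a list of (rec_off, rec_on) pairs plus ground truth with the
    per-hemisphere exponents and beta-peak heights.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs, truth_h = [], []
    for h in range(cfg.n_hemispheres):
        chi_off = rng.normal(cfg.chi_off_mean, cfg.chi_off_sd)
        chi_off = float(np.clip(chi_off, 0.4, 2.5))
        chi_on = float(np.clip(chi_off + rng.normal(cfg.delta_chi_mean,
                                                    cfg.delta_chi_sd), 0.2, 3.0))
        cf = float(rng.uniform(*cfg.beta_cf_range))
        sig = float(rng.uniform(*cfg.beta_sigma_range))
        h_off = float(np.clip(rng.normal(*cfg.beta_height_off), 0.05, None))
        h_on = float(np.clip(h_off + rng.normal(cfg.delta_beta_mean,
                                                cfg.delta_beta_sd), 0.0, None))
        dbs_b = {"plateau_level": 1.0, "freqs": cfg.dbs_harmonics,
                 "harmonic_amps": (0.5, 1.0)} if cfg.dbs_plateau else None
        rec_off, rec_on, _ = gen_patient_dataset(
            chi_off, chi_on, fs=cfg.fs, duration_s=cfg.duration_s,
            beta_a=(cf, h_off, sig), beta_b=(cf, h_on, sig),
            mains_amp=cfg.mains_amp, dbs_b=dbs_b,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        pairs.append((rec_off, rec_on))
        truth_h.append({"hemisphere": h, "chi_off": chi_off, "chi_on": chi_on,
                        "beta_cf": cf, "beta_h_off": h_off, "beta_h_on": h_on})
    truth = {"condition": cfg.condition, "n_hemispheres": cfg.n_hemispheres,
             "delta_chi_mean": cfg.delta_chi_mean, "hemispheres": truth_h}
    return pairs, truth
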