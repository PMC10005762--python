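"""End-to-end analysis drivers.

Three drivers mirror the three analyses this package implements:

* :func:`run_rodent_ei` — spike-state-conditioned exponents in rodent-style
  STN recordings during slow-wave activity (fixed-mode fit, 30–100 Hz),
  contrasted with a random-intercept mixed model across animals;
* :func:`run_medication_contrast` — per-hemisphere ON/OFF-levodopa exponent
  (fixed mode, 40–90 Hz), periodic beta power (knee mode, 5–90 Hz) and six
  band powers, contrasted with paired permutation t-tests;
* :func:`run_dbs_contrast` — the same for ON/OFF 130 Hz stimulation, with
  the exponent fit lowered to 10–50 Hz to stay below the stimulation-induced
  spectral plateau.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .io import Recording, SpikeTrain
from .preprocess import butterworth_filter, local_average_reference, resample_signal
from .spectral import (BANDS, Spectrum, band_power, interpolate_mains,
                       morlet_power, time_average_psd)
from .specparam import (SpecparamSettings, fit_aperiodic, fit_model,
                        largest_peak_in_band)
from .spike_state import build_epoch_grid, state_psd
from .stats import (ContrastResult, lme_random_intercept,
                    paired_permutation_ttest_family, spearman_corr)

logger = logging.getLogger(__name__)

__all__ = [
    "RodentConfig",
    "PatientConfig",
    "AnalysisReport",
    "run_rodent_ei",
    "run_medication_contrast",
    "run_dbs_contrast",
]


@dataclass
class RodentConfig:
    """Stage parameters for the rodent spike-state analysis."""

    epoch_len_s: float = 0.25          # spike-state epoch length
    lo_percentile: float = 25.0        # "low spiking" below this count percentile
    hi_percentile: float = 75.0        # "high spiking" above this one
    f_lo: float = 1.0                  # decomposition grid (Hz)
    f_hi: float = 100.0
    n_cycles: float = 50.0             # fixed wavelet cycle count
    norm_band: tuple[float, float] = (1.0, 100.0)   # epoch-PSD normalisation
    fit_range: tuple[float, float] = (30.0, 100.0)  # aperiodic fit (fixed mode)
    power_band: tuple[float, float] = (30.0, 100.0) # mean-power band
    lowpass_hz: float = 300.0          # LFP anti-spike lowpass
    lowpass_order: int = 3
    resample_fs: float = 2048.0
    reference: str = "none"            # "none" | "local_average"
    r2_floor: float = 0.9              # fits below this are flagged, not dropped
    seed: int = 0

    def __post_init__(self):
        _validate_common(self)
        if not 0 <= self.lo_percentile < self.hi_percentile <= 100:
            raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch length must be positive")


@dataclass
class PatientConfig:
    """Stage parameters for the human ON/OFF contrasts."""

    highpass_hz: float = 1.0
    highpass_order: int = 3
    f_lo: float = 1.0
    f_hi: float = 90.0
    n_cycles: float = 50.0
    norm_band: tuple[float, float] = (1.0, 90.0)
    mains_band: tuple[float, float] = (47.0, 53.0)   # excised and interpolated
    exp_fit_range: tuple[float, float] = (40.0, 90.0)  # fixed-mode exponent
    knee_fit_range: tuple[float, float] = (5.0, 90.0)  # knee-mode periodic model
    beta_select_band: tuple[float, float] = (13.0, 35.0)  # largest-peak window
    bands: dict = field(default_factory=lambda: dict(BANDS))
    n_perms: int = 50_000
    sweep_ranges: tuple = ()           # optional fit-range robustness sweep
    r2_floor: float = 0.9
    seed: int = 0

    def __post_init__(self):
        _validate_common(self)


def _validate_common(cfg) -> None:
    for rng_attr in ("fit_range", "power_band", "exp_fit_range",
                     "knee_fit_range", "norm_band"):
        rng = getattr(cfg, rng_attr, None)
        if rng is not None and rng[0] >= rng[1]:
            raise ValueError(f"{rng_attr} lower bound must be below upper bound")


@dataclass
class AnalysisReport:
    """Per-channel/hemisphere table plus contrast statistics."""

    kind: str
    table: pd.DataFrame
    contrasts: dict
    correlations: dict
    config: dict
    seed: int
    version: str = __version__
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "table": self.table.to_dict(orient="list"),
            "contrasts": self.contrasts,
            "correlations": self.correlations,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "warnings": self.warnings,
        }


def _stage(name: str, channel: str):
    """Context string for stage-level error reporting."""
    return f"stage '{name}', channel '{channel}'"


def _preprocess_rodent(rec: Recording, cfg: RodentConfig) -> Recording:
    if cfg.lowpass_hz < rec.fs / 2:
        rec = butterworth_filter(rec, "lowpass", cfg.lowpass_hz, cfg.lowpass_order)
    if cfg.resample_fs < rec.fs:
        rec = resample_signal(rec, cfg.resample_fs)
    return rec


def run_rodent_ei(recordings: list[Recording],
                  spike_trains: list[list[SpikeTrain]],
                  cfg: RodentConfig | None = None) -> AnalysisReport:
    """Spike-state-conditioned exponent/power analysis across animals.

    One Recording (plus its unit spike trains) per animal.  Per LFP channel
    and STN unit: label 250 ms epochs by the unit's firing percentiles, form
    the state-average normalised PSDs, fit the fixed-mode aperiodic model on
    the fit range and take the mean band power; contrast low vs high states
    with a random-intercept (animal) mixed model, and correlate exponents
    with power per state and pooled.
    """
    cfg = cfg or RodentConfig()
    rows: list[dict] = []
    warns: list[str] = []
    for animal_idx, (rec, trains) in enumerate(zip(recordings, spike_trains)):
        stn_units = [t for t in trains if "gpe" not in t.unit_id.lower()]
        kept = [t for t in stn_units if t.passes_qc]
        for t in stn_units:
            if not t.passes_qc:
                warns.append(f"unit {t.unit_id} excluded: frac_short_isi="
                             f"{t.frac_short_isi:.3f}")
        if not kept:
            warns.append(f"animal {animal_idx}: no units passed isolation QC")
            continue
        try:
            rec = _preprocess_rodent(rec, cfg)
        except Exception as exc:
            raise RuntimeError(f"{_stage('preprocess', rec.channel_ids[0])}: {exc}"
                               ) from exc
        duration = rec.duration_s
        grid = build_epoch_grid(kept, duration, cfg.epoch_len_s,
                                cfg.lo_percentile, cfg.hi_percentile)
        for ch in rec.channel_ids:
            if cfg.reference == "local_average":
                x = local_average_reference(rec, ch)
            else:
                x = rec.channel(ch)
            try:
                tf = morlet_power(x, rec.fs, cfg.f_lo, cfg.f_hi,
                                  n_cycles=cfg.n_cycles)
            except Exception as exc:
                raise RuntimeError(f"{_stage('morlet', ch)}: {exc}") from exc
            for unit in kept:
                labels = grid.labels_for(unit.unit_id)
                for state in ("high", "low"):
                    try:
                        psd = state_psd(tf, labels, state, cfg.norm_band,
                                        cfg.epoch_len_s)
                    except ValueError as exc:
                        warns.append(f"{_stage('state_psd', ch)}: {exc}")
                        continue
                    ap = fit_aperiodic(psd, cfg.fit_range, mode="fixed")
                    power = band_power(psd, cfg.power_band)
                    if ap.r2 < cfg.r2_floor:
                        warns.append(f"low-R2 fit ({ap.r2:.3f}) for {ch}/"
                                     f"{unit.unit_id}/{state}")
                    rows.append({"animal": animal_idx, "channel": ch,
                                 "unit": unit.unit_id, "state": state,
                                 "exponent": ap.exponent, "offset": ap.offset,
                                 "power": power, "r2": ap.r2})
    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("no analysable channel/unit pairs")

    # low - high contrasts, animal as random intercept
    cond = (table["state"] == "low").astype(float).to_numpy()
    contrasts = {
        "exponent_low_minus_high": asdict(lme_random_intercept(
            table["exponent"].to_numpy(), cond, table["animal"].to_numpy())),
        "power_low_minus_high": asdict(lme_random_intercept(
            table["power"].to_numpy(), cond, table["animal"].to_numpy())),
    }
    correlations = {}
    for state in ("high", "low"):
        sub = table[table["state"] == state]
        correlations[f"exponent_vs_power_{state}"] = asdict(
            spearman_corr(sub["exponent"].to_numpy(), sub["power"].to_numpy()))
    correlations["exponent_vs_power_pooled"] = asdict(
        spearman_corr(table["exponent"].to_numpy(), table["power"].to_numpy()))
    return AnalysisReport(kind="rodent_ei", table=table, contrasts=contrasts,
                          correlations=correlations, config=asdict(cfg),
                          seed=cfg.seed, warnings=warns)


def _hemisphere_measures(rec: Recording, cfg: PatientConfig,
                         exp_fit_range: tuple[float, float]) -> dict:
    """All per-recording spectral measures for one hemisphere/condition."""
    rec = butterworth_filter(rec, "highpass", cfg.highpass_hz, cfg.highpass_order)
    x = rec.data[0]
    tf = morlet_power(x, rec.fs, cfg.f_lo, cfg.f_hi, n_cycles=cfg.n_cycles)
    psd = time_average_psd(tf, norm_band=cfg.norm_band)
    psd = interpolate_mains(psd, cfg.mains_band)

    out = {}
    ap_fixed = fit_aperiodic(psd, exp_fit_range, mode="fixed")
    out["exponent"] = ap_fixed.exponent
    out["exponent_r2"] = ap_fixed.r2
    knee_model = fit_model(psd, cfg.knee_fit_range,
                           SpecparamSettings(aperiodic_mode="knee"))
    peak = largest_peak_in_band(knee_model, cfg.beta_select_band)
    out["periodic_beta"] = peak.pw if peak is not None else 0.0
    out["beta_cf"] = peak.cf if peak is not None else np.nan
    out["knee_r2"] = knee_model.r2
    for name, band in cfg.bands.items():
        out[f"power_{name}"] = band_power(psd.slice(cfg.knee_fit_range),
                                          band, aperiodic=knee_model.aperiodic)
    for rng in cfg.sweep_ranges:
        ap = fit_aperiodic(psd, tuple(rng), mode="fixed")
        out[f"exponent_{rng[0]:g}_{rng[1]:g}"] = ap.exponent
    return out


def _run_patient_contrast(pairs, cfg: PatientConfig, kind: str,
                          exp_fit_range: tuple[float, float]) -> AnalysisReport:
    rows, warns = [], []
    for h, pair in enumerate(pairs):
        if pair is None or pair[0] is None or pair[1] is None:
            warns.append(f"hemisphere {h}: missing pair member; skipped")
            continue
        for cond_name, rec in zip(("off", "on"), pair):
            try:
                meas = _hemisphere_measures(rec, cfg, exp_fit_range)
            except Exception as exc:
                raise RuntimeError(
                    f"{_stage('hemisphere_measures', f'h{h}/{cond_name}')}: {exc}"
                ) from exc
            if meas["exponent_r2"] < cfg.r2_floor:
                warns.append(f"hemisphere {h} {cond_name}: exponent fit "
                             f"R2={meas['exponent_r2']:.3f} below floor")
            rows.append({"hemisphere": h, "condition": cond_name, **meas})
    table = pd.DataFrame(rows)
    if table.empty:
        raise RuntimeError("no complete hemisphere pairs")
    off = table[table["condition"] == "off"].set_index("hemisphere")
    on = table[table["condition"] == "on"].set_index("hemisphere")

    def diff(col):
        return (on[col] - off[col]).to_numpy()

    # exponent and periodic beta each tested alone; the six band powers as
    # one max-|t|-corrected family
    contrasts = {}
    exp_res = paired_permutation_ttest_family(
        diff("exponent")[:, None], n_perms=cfg.n_perms, seed=cfg.seed)[0]
    contrasts["exponent_on_minus_off"] = asdict(exp_res)
    contrasts["periodic_beta_on_minus_off"] = asdict(
        paired_permutation_ttest_family(diff("periodic_beta")[:, None],
                                        n_perms=cfg.n_perms, seed=cfg.seed + 1)[0])
    band_names = list(cfg.bands)
    band_diffs = np.column_stack([diff(f"power_{b}") for b in band_names])
    fam = paired_permutation_ttest_family(band_diffs, n_perms=cfg.n_perms,
                                          seed=cfg.seed + 2)
    for name, res in zip(band_names, fam):
        contrasts[f"power_{name}_on_minus_off"] = asdict(res)
    contrasts["prop_exponent_higher_on"] = float(np.mean(diff("exponent") > 0))

    def safe_corr(x, y, name):
        try:
            return asdict(spearman_corr(x, y))
        except ValueError as exc:
            warns.append(f"correlation '{name}' undefined: {exc}")
            return {"rho": float("nan"), "p": float("nan"), "n": int(len(x))}

    correlations = {
        "d_exponent_vs_d_periodic_beta": safe_corr(
            diff("exponent"), diff("periodic_beta"),
            "d_exponent_vs_d_periodic_beta"),
    }
    for b in ("beta", "low_beta", "high_beta"):
        correlations[f"d_exponent_vs_d_power_{b}"] = safe_corr(
            diff("exponent"), diff(f"power_{b}"), f"d_exponent_vs_d_power_{b}")

    sweep = {}
    for rng in cfg.sweep_ranges:
        col = f"exponent_{rng[0]:g}_{rng[1]:g}"
        res = paired_permutation_ttest_family(
            diff(col)[:, None], n_perms=min(cfg.n_perms, 10_000),
            seed=cfg.seed + 3)[0]
        sweep[col] = asdict(res)
    if sweep:
        contrasts["fit_range_sweep"] = sweep

    cfg_echo = asdict(cfg)
    cfg_echo["exp_fit_range"] = tuple(exp_fit_range)
    return AnalysisReport(kind=kind, table=table, contrasts=contrasts,
                          correlations=correlations, config=cfg_echo,
                          seed=cfg.seed, warnings=warns)


def run_medication_contrast(pairs, cfg: PatientConfig | None = None) -> AnalysisReport:
    """ON vs OFF levodopa: exponent 40–90 Hz (fixed), periodic beta (knee,
    5–90 Hz), six corrected band powers; paired permutation contrasts."""
    cfg = cfg or PatientConfig()
    return _run_patient_contrast(pairs, cfg, "medication_contrast",
                                 cfg.exp_fit_range)


def run_dbs_contrast(pairs, cfg: PatientConfig | None = None) -> AnalysisReport:
    """ON vs OFF 130 Hz stimulation: as the medication driver but with the
    exponent fit range lowered to 10–50 Hz to avoid the ON-DBS plateau."""
    cfg = cfg or PatientConfig(exp_fit_range=(10.0, 50.0))
    if cfg.exp_fit_range != (10.0, 50.0):
        logger.info("DBS contrast with non-default exponent fit range %s",
                    cfg.exp_fit_range)
    return _run_patient_contrast(pairs, cfg, "dbs_contrast", cfg.exp_fit_range)
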