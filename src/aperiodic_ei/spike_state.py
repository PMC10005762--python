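"""Epoch-level firing-state labels from spike trains.

Spikes are counted in consecutive non-overlapping epochs (250 ms by
default); epochs above the 75th percentile of a unit's counts are labelled
"high" spiking, below the 25th percentile "low", everything else "mid".
State-conditioned PSDs built from these labels are the engine of the
excitation/inhibition contrast: during slow-wave activity, epochs of high
STN firing correspond to strong cortical excitation and weak pallidal
inhibition of STN, and vice versa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import SpikeTrain
from .spectral import Spectrum, TFPower, average_psd, epoch_psd

logger = logging.getLogger(__name__)

__all__ = [
    "EpochGrid",
    "count_spikes_per_epoch",
    "hazen_percentile",
    "percentile_classify",
    "state_psd",
]

#: Percentile convention: linear interpolation of order statistics at
#: probabilities (k - 0.5)/n ("hazen"), matching the original analysis
#: environment's default.
PERCENTILE_METHOD = "hazen"


@dataclass
class EpochGrid:
    """Per-unit spike counts and firing-state labels on a shared epoch grid."""

    epoch_len_s: float
    n_epochs: int
    unit_ids: list[str]
    counts: np.ndarray              # (n_epochs, n_units) int
    labels: np.ndarray              # (n_epochs, n_units) of {"high","low","mid"}
    thresholds: dict[str, tuple[float, float]]   # unit -> (lo, hi) count thresholds

    def __post_init__(self):
        if self.counts.shape != (self.n_epochs, len(self.unit_ids)):
            raise ValueError("counts must be (n_epochs, n_units)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        both = (self.labels == "high") & (self.labels == "low")
        assert not both.any()

    def labels_for(self, unit_id: str) -> np.ndarray:
        return self.labels[:, self.unit_ids.index(str(unit_id))]


def count_spikes_per_epoch(train: SpikeTrain, duration_s: float,
                           epoch_len_s: float = 0.25) -> np.ndarray:
    """Spike counts in consecutive non-overlapping epochs.

    Epoch e covers [e*L, (e+1)*L): a spike at an exact boundary belongs to
    the later epoch.  The trailing partial epoch is dropped; spikes beyond
    ``duration_s`` are ignored with a warning.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if epoch_len_s <= 0:
        raise ValueError("epoch length must be positive")
    n_epochs = int(np.floor(duration_s / epoch_len_s + 1e-9))
    times = train.times_s
    beyond = times >= n_epochs * epoch_len_s
    if np.any(beyond):
        logger.warning("unit %s: %d spikes beyond the analysed duration ignored",
                       train.unit_id, int(beyond.sum()))
        times = times[~beyond]
    idx = np.floor(times / epoch_len_s + 1e-12).astype(int)
    counts = np.bincount(idx, minlength=n_epochs)[:n_epochs]
    return counts


def hazen_percentile(data: np.ndarray, q: float | np.ndarray) -> float | np.ndarray:
    """Percentile by linear interpolation at probabilities (k - 0.5)/n."""
    return np.percentile(np.asarray(data, dtype=float), q,
                         method=PERCENTILE_METHOD)


def percentile_classify(counts: np.ndarray, lo: float = 25.0,
                        hi: float = 75.0) -> tuple[np.ndarray, tuple[float, float]]:
    """Label epochs by where their count sits in the unit's own distribution.

    Strict inequalities: count > hi-threshold -> "high"; count <
    lo-threshold -> "low"; ties at a threshold stay "mid".  A degenerate
    all-equal unit yields all "mid" with a warning.
    """
    counts = np.asarray(counts)
    if counts.size < 8:
        raise ValueError("need at least 8 epochs to classify firing states")
    if not 0 <= lo < hi <= 100:
        raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")
    lo_thr, hi_thr = (float(hazen_percentile(counts, lo)),
                      float(hazen_percentile(counts, hi)))
    labels = np.full(counts.shape, "mid", dtype=object)
    if np.all(counts == counts.flat[0]):
        warnings.warn("all epoch counts equal; no high/low states for this unit",
                      stacklevel=2)
        return labels, (lo_thr, hi_thr)
    labels[counts > hi_thr] = "high"
    labels[counts < lo_thr] = "low"
    return labels, (lo_thr, hi_thr)


def build_epoch_grid(trains: list[SpikeTrain], duration_s: float,
                     epoch_len_s: float = 0.25, lo: float = 25.0,
                     hi: float = 75.0) -> EpochGrid:
    """Counts and labels for several units on one shared epoch grid."""
    if not trains:
        raise ValueError("no spike trains supplied")
    counts_cols, labels_cols, thresholds = [], [], {}
    for train in trains:
        c = count_spikes_per_epoch(train, duration_s, epoch_len_s)
        lab, thr = percentile_classify(c, lo, hi)
        counts_cols.append(c)
        labels_cols.append(lab)
        thresholds[train.unit_id] = thr
    counts = np.stack(counts_cols, axis=1)
    labels = np.stack(labels_cols, axis=1)
    return EpochGrid(epoch_len_s=epoch_len_s, n_epochs=counts.shape[0],
                     unit_ids=[t.unit_id for t in trains], counts=counts,
                     labels=labels, thresholds=thresholds)


def state_psd(tf: TFPower, labels: np.ndarray, state: str,
              norm_band: tuple[float, float] | None = (1.0, 100.0),
              epoch_len_s: float = 0.25) -> Spectrum:
    """Mean of the per-epoch normalised PSDs whose label equals ``state``.

    ``labels`` must be aligned to the same epoch grid that
    :func:`aperiodic_ei.spectral.epoch_psd` produces for ``tf``.
    """
    spectra = epoch_psd(tf, epoch_len_s=epoch_len_s, norm_band=norm_band)
    labels = np.asarray(labels, dtype=object)
    if len(spectra) < labels.size:
        raise ValueError("labels outnumber the epochs available in tf")
    selected = [s for s, lab in zip(spectra, labels) if lab == state]
    if not selected:
        raise ValueError(f"no epochs labelled '{state}'")
    return average_psd(selected)
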