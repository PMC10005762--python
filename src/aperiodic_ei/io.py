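"""Reading recordings, spike-event lists and run configurations; writing
spectra, fits and results tables.

Signal formats: EDF (via ``mne``, an optional dependency) or a flat binary
dialect — little-endian float32, channel-major, with a JSON sidecar
``<stem>.json`` holding ``fs``, ``channel_ids`` and optional ``geometry``.
Spike events are CSV with columns ``unit_id, time_s``.  Outputs are TSV for
spectra/tables and JSON for fits and statistics.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np

from .spectral import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "SpikeTrain",
    "read_timeseries",
    "write_timeseries",
    "read_spike_events",
    "write_spike_events",
    "write_results",
    "read_spectrum",
    "SHORT_ISI_S",
    "MAX_FRAC_SHORT_ISI",
]

#: Inter-spike intervals shorter than this indicate contaminated isolation.
SHORT_ISI_S = 0.002
#: Units with a larger fraction of short ISIs are excluded by default.
MAX_FRAC_SHORT_ISI = 0.01


@dataclass
class Recording:
    """Multichannel time series.

    data is (n_channels, n_samples); fs in Hz; channel_ids are unique ordered
    labels; geometry, when present, maps each channel id to
    ``{"array": int, "position_um": float}``.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str]
    geometry: dict[str, dict] | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids must match the number of rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.geometry is not None:
            missing = set(self.channel_ids) - set(self.geometry)
            if missing:
                raise ValueError(f"geometry missing channels: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(str(channel_id))]


@dataclass
class SpikeTrain:
    """Sorted event times (s, relative to recording start) for one unit."""

    unit_id: str
    times_s: np.ndarray
    source_channel: str | None = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size and np.any(self.times_s < 0):
            raise ValueError(f"unit {self.unit_id}: negative spike times")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError(f"unit {self.unit_id}: times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.times_s.size

    @property
    def frac_short_isi(self) -> float:
        """Fraction of inter-spike intervals below 2 ms (isolation QC)."""
        if self.times_s.size < 2:
            return 0.0
        isis = np.diff(self.times_s)
        return float(np.mean(isis < SHORT_ISI_S))

    @property
    def passes_qc(self) -> bool:
        return self.frac_short_isi < MAX_FRAC_SHORT_ISI


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_timeseries(path: str | Path, format_hint: str | None = None) -> Recording:
    """Read a recording from EDF or flat binary + JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or ("edf" if path.suffix.lower() == ".edf" else "binary")
    if fmt == "edf":
        return _read_edf(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing JSON sidecar for flat binary file: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "channel_ids"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required key '{key}'")
    raw = np.fromfile(path, dtype="<f4")
    n_ch = len(meta["channel_ids"])
    if n_ch == 0 or raw.size % n_ch:
        raise ValueError("sample count is not a multiple of the channel count")
    data = raw.reshape(n_ch, -1).astype(float)
    if not np.all(np.isfinite(data)):
        raise ValueError("recording contains non-finite samples")
    return Recording(data=data, fs=float(meta["fs"]),
                     channel_ids=list(meta["channel_ids"]),
                     geometry=meta.get("geometry"))


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(data=raw.get_data(), fs=float(raw.info["sfreq"]),
                     channel_ids=list(raw.ch_names))


def write_timeseries(rec: Recording, path: str | Path) -> None:
    """Write a recording in the flat-binary + JSON sidecar dialect."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    meta = {"fs": rec.fs, "channel_ids": rec.channel_ids}
    if rec.geometry is not None:
        meta["geometry"] = rec.geometry
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_spike_events(path: str | Path) -> list[SpikeTrain]:
    """Read a CSV of (unit_id, time_s) rows into one SpikeTrain per unit.

    Unsorted times are sorted with a log note; negative times are an error.
    """
    path = Path(path)
    by_unit: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        if not {"unit_id", "time_s"} <= set(reader.fieldnames):
            raise ValueError("spike CSV must have columns unit_id, time_s")
        for row in reader:
            t = float(row["time_s"])
            if t < 0:
                raise ValueError(f"negative spike time {t} for unit {row['unit_id']}")
            by_unit.setdefault(str(row["unit_id"]), []).append(t)
    trains = []
    for unit_id in by_unit:
        times = np.asarray(by_unit[unit_id])
        if np.any(np.diff(times) < 0):
            logger.info("unit %s: spike times unsorted in file; sorting", unit_id)
            times = np.sort(times)
        times = np.unique(times)
        trains.append(SpikeTrain(unit_id=unit_id, times_s=times))
    return trains


def write_spike_events(trains: list[SpikeTrain], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["unit_id", "time_s"])
        for train in trains:
            for t in train.times_s:
                writer.writerow([train.unit_id, repr(float(t))])


def _spectrum_to_tsv(s: Spectrum, path: Path) -> None:
    header = {
        "normalized_band": s.normalized_band,
        "mains_interpolated": s.mains_interpolated,
        "flattened": s.flattened,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        fh.write("frequency_hz\tpower\n")
        for f, p in zip(s.frequencies, s.power):
            fh.write(f"{float(f)!r}\t{float(p)!r}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    freqs, power = [], []
    header = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                header = json.loads(line[1:])
                continue
            if line.startswith("frequency_hz"):
                continue
            f, p = line.split("\t")
            freqs.append(float(f))
            power.append(float(p))

    def _tup(v):
        return tuple(v) if isinstance(v, list) else v

    return Spectrum(np.asarray(freqs), np.asarray(power),
                    normalized_band=_tup(header.get("normalized_band")),
                    mains_interpolated=_tup(header.get("mains_interpolated")),
                    flattened=bool(header.get("flattened", False)))


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    return obj


def write_results(obj, path: str | Path) -> None:
    """Write a Spectrum as TSV, anything else (fits, stats, tables) as JSON
    with deterministic key ordering."""
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory for {path}") from exc
    if isinstance(obj, Spectrum):
        _spectrum_to_tsv(obj, path)
        return
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")
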