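"""Recording, spike and event I/O for single-shank laminar probe sessions.

Conventions owned here and used everywhere else in the package:

* all times are seconds (float), origin at recording start, intervals
  half-open ``[start, end)``;
* all depths are micrometres, 0 at the shallowest recording site,
  increasing downward;
* all frequencies are Hz;
* continuous voltage is stored channels x time as int16 ADC counts with a
  microvolt scale factor, interleaved sample-major on disk
  (Neuroscope-style ``.dat`` / ``.lfp`` flat binary);
* channel order in files is geometric order, top to bottom.  A hardware
  permutation, when present in the descriptor, is applied on load.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when a file on disk does not match its declared geometry."""


class ConfigurationError(ValueError):
    """Raised for inconsistent descriptor / configuration input."""


# --------------------------------------------------------------------------
# containers


@dataclass
class ProbeRecording:
    """Continuous multichannel voltage plus channel geometry.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in ADC counts (int16) or already-scaled microvolts (float).
    fs : float
        Sampling rate, Hz.
    channel_depth_um : ndarray, shape (n_channels,)
        Depth of each site, micrometres, strictly increasing downward.
    uv_per_bit : float
        Microvolts per ADC count (ignored for float input).
    """

    samples: np.ndarray
    fs: float
    channel_depth_um: np.ndarray
    uv_per_bit: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.channel_depth_um = np.asarray(self.channel_depth_um, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be 2-D (channels x time)")
        if self.channel_depth_um.shape[0] != self.samples.shape[0]:
            raise ConfigurationError(
                f"{self.samples.shape[0]} channels but "
                f"{self.channel_depth_um.shape[0]} depths in geometry"
            )
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if np.any(np.diff(self.channel_depth_um) <= 0):
            raise ConfigurationError("channel depths must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def pitch_um(self) -> float:
        return float(np.median(np.diff(self.channel_depth_um)))

    def voltage_uv(self, channels=None, t_start: float = 0.0, t_stop: float | None = None) -> np.ndarray:
        """Scaled voltage (microvolts, float64) for a channel subset / window."""
        i0 = int(round(t_start * self.fs))
        i1 = self.n_samples if t_stop is None else int(round(t_stop * self.fs))
        sl = slice(None) if channels is None else channels
        out = np.asarray(self.samples[sl, i0:i1], dtype=np.float64)
        if np.issubdtype(self.samples.dtype, np.integer):
            out *= self.uv_per_bit
        return out

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class SpikeDataset:
    """Sorted spike trains with per-unit mean wideband waveforms.

    ``spike_times`` maps unit id -> sorted spike times (s).  ``waveforms``
    maps unit id -> mean waveform (single channel, wideband sampling rate);
    may be empty when only times are available.
    """

    spike_times: dict[int, np.ndarray]
    waveforms: dict[int, np.ndarray] = field(default_factory=dict)
    waveform_fs: float = 20000.0
    peak_channel: dict[int, int] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for uid, t in self.spike_times.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
                raise ConfigurationError(f"unit {uid}: spike times must be sorted, non-negative")
            self.spike_times[uid] = t

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.spike_times)

    def n_spikes(self, uid: int) -> int:
        return int(self.spike_times[uid].size)

    def rate(self, uid: int, duration_s: float) -> float:
        return self.n_spikes(uid) / duration_s


#: recognised event types
EVENT_TYPES = ("LIGHT_VISUAL", "LIGHT_OPTO", "OTHER")


def make_event_table(times, types, durations=None, intensity=None) -> pd.DataFrame:
    """Build a sorted event table (columns: time_s, type, duration_s, intensity)."""
    df = pd.DataFrame(
        {
            "time_s": np.asarray(times, dtype=float),
            "type": list(types),
            "duration_s": 0.0 if durations is None else np.asarray(durations, dtype=float),
            "intensity": 1.0 if intensity is None else np.asarray(intensity, dtype=float),
        }
    )
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# flat binary recording files


def write_recording(rec: ProbeRecording, path: str | Path) -> Path:
    """Write interleaved int16 flat binary plus a JSON geometry descriptor.

    ``path`` is the binary file (conventionally ``.dat`` for wideband,
    ``.lfp`` for downsampled); the descriptor is written next to it with a
    ``.json`` suffix appended to the stem.
    """
    path = Path(path)
    data = rec.samples
    if not np.issubdtype(data.dtype, np.integer):
        data = np.clip(np.round(data / rec.uv_per_bit), -32768, 32767)
    data.astype("<i2").T.tofile(path)  # sample-major interleaved
    desc = {
        "n_channels": rec.n_channels,
        "fs_hz": rec.fs,
        "uv_per_bit": rec.uv_per_bit,
        "channel_depth_um": rec.channel_depth_um.tolist(),
        "dtype": "int16",
        "meta": _jsonable(rec.meta),
    }
    descriptor_path(path).write_text(json.dumps(desc, indent=1))
    return path


def descriptor_path(binary_path: str | Path) -> Path:
    binary_path = Path(binary_path)
    return binary_path.with_suffix(binary_path.suffix + ".json")


def load_recording(path: str | Path, geometry_descriptor: str | Path | dict | None = None,
                   mmap: bool = True) -> ProbeRecording:
    """Load a flat binary int16 recording.

    The geometry descriptor (JSON file or dict) must give ``n_channels``,
    ``fs_hz``, ``uv_per_bit`` and ``channel_depth_um``; an optional
    ``channel_map`` permutation converts hardware order to geometric order.
    Data access is windowed/lazy via memory mapping: any time window read
    yields identical values regardless of access pattern.
    """
    path = Path(path)
    if geometry_descriptor is None:
        geometry_descriptor = descriptor_path(path)
    if isinstance(geometry_descriptor, (str, Path)):
        gp = Path(geometry_descriptor)
        if not gp.exists():
            raise ConfigurationError(f"missing geometry descriptor: {gp}")
        desc = json.loads(gp.read_text())
    else:
        desc = dict(geometry_descriptor)
    n_ch = int(desc["n_channels"])
    nbytes = path.stat().st_size
    if nbytes % (2 * n_ch) != 0:
        raise FormatError(
            f"{path}: size {nbytes} B is not a whole number of {n_ch}-channel int16 frames"
        )
    n_samples = nbytes // (2 * n_ch)
    raw = np.memmap(path, dtype="<i2", mode="r", shape=(n_samples, n_ch))
    data = raw.T if mmap else np.ascontiguousarray(raw.T)
    if "channel_map" in desc and desc["channel_map"] is not None:
        data = data[np.asarray(desc["channel_map"], dtype=int)]
    return ProbeRecording(
        samples=data,
        fs=float(desc["fs_hz"]),
        channel_depth_um=np.asarray(desc["channel_depth_um"], dtype=float),
        uv_per_bit=float(desc.get("uv_per_bit", 1.0)),
        meta=desc.get("meta", {}),
    )


def downsample_lfp(rec: ProbeRecording, target_fs: float) -> ProbeRecording:
    """Anti-aliased integer-ratio downsampling (wideband -> LFP).

    A zero-phase FIR low-pass at the new Nyquist frequency is applied
    before decimation (polyphase).  ``target_fs`` must divide ``rec.fs``.
    """
    from scipy.signal import resample_poly

    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError(
            f"target_fs {target_fs} is not an integer divisor of fs {rec.fs}"
        )
    q = int(round(ratio))
    if q == 1:
        return rec
    x = rec.voltage_uv()
    y = resample_poly(x, 1, q, axis=1)
    y = y[:, : int(rec.n_samples // q)]
    out = np.clip(np.round(y / rec.uv_per_bit), -32768, 32767).astype(np.int16)
    return ProbeRecording(out, target_fs, rec.channel_depth_um.copy(),
                          uv_per_bit=rec.uv_per_bit, meta=dict(rec.meta))


# --------------------------------------------------------------------------
# delimited-text spike / event / interval tables


def save_spikes(spikes: SpikeDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [(uid, t) for uid in spikes.unit_ids for t in spikes.spike_times[uid]]
    df = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    df.to_csv(directory / "spikes.tsv", sep="\t", index=False, float_format="%.6f")
    meta = pd.DataFrame(
        {
            "unit_id": spikes.unit_ids,
            "peak_channel": [spikes.peak_channel.get(u, -1) for u in spikes.unit_ids],
            "label": [spikes.labels.get(u, "") for u in spikes.unit_ids],
        }
    )
    meta.to_csv(directory / "units.csv", index=False)
    if spikes.waveforms:
        wf = pd.DataFrame(
            {str(u): pd.Series(spikes.waveforms[u]) for u in sorted(spikes.waveforms)}
        )
        wf.insert(0, "waveform_fs", spikes.waveform_fs)
        wf.to_csv(directory / "waveforms.csv", index=False)
    return directory


def load_spikes(directory: str | Path) -> SpikeDataset:
    directory = Path(directory)
    f = directory / "spikes.tsv"
    if not f.exists():
        raise ConfigurationError(f"missing spike table: {f}")
    df = pd.read_csv(f, sep="\t")
    times = {
        int(uid): np.sort(np.asarray(g["time_s"], dtype=float))
        for uid, g in df.groupby("unit_id")
    }
    peak, labels = {}, {}
    meta_f = directory / "units.csv"
    if meta_f.exists():
        meta = pd.read_csv(meta_f)
        for _, r in meta.iterrows():
            uid = int(r["unit_id"])
            times.setdefault(uid, np.empty(0))
            peak[uid] = int(r["peak_channel"])
            labels[uid] = "" if pd.isna(r.get("label", "")) else str(r.get("label", ""))
    waveforms, wf_fs = {}, 20000.0
    wf_f = directory / "waveforms.csv"
    if wf_f.exists():
        wf = pd.read_csv(wf_f)
        wf_fs = float(wf.pop("waveform_fs").iloc[0])
        for col in wf.columns:
            waveforms[int(col)] = np.asarray(wf[col].dropna(), dtype=float)
    return SpikeDataset(times, waveforms, wf_fs, peak, labels)


def save_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, index=False, float_format="%.6f")
    return path


def load_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"missing event table: {path}")
    return pd.read_csv(path)


def save_intervals(intervals, path: str | Path) -> Path:
    """Write labeled intervals [(start, end, label), ...] as CSV."""
    df = pd.DataFrame(intervals, columns=["start_s", "end_s", "label"])
    df.to_csv(path, index=False, float_format="%.6f")
    return Path(path)


def load_intervals(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    return [(float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples()]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_json(obj, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))
    return Path(path)


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
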