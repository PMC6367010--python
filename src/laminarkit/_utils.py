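"""Shared numeric helpers: filtering, intervals, windowed FFT, seeding."""

from __future__ import annotations

import numpy as np
from scipy import signal


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4,
             axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def lowpass(x: np.ndarray, fs: float, hi: float, order: int = 4, axis: int = -1) -> np.ndarray:
    sos = signal.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def envelope(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Amplitude envelope via the analytic signal."""
    return np.abs(signal.hilbert(x, axis=axis))


def smooth_boxcar(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average over n samples (edge-truncated)."""
    n = max(int(n), 1)
    kernel = np.ones(n) / n
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


# --------------------------------------------------------------------------
# half-open intervals [start, end)


def intervals_total(intervals) -> float:
    return float(sum(e - s for s, e, *_ in intervals))


def in_intervals(t: np.ndarray, intervals) -> np.ndarray:
    """Boolean mask of times falling in any half-open interval."""
    t = np.asarray(t)
    mask = np.zeros(t.shape, dtype=bool)
    for s, e, *_ in intervals:
        mask |= (t >= s) & (t < e)
    return mask


def restrict_times(t: np.ndarray, intervals) -> np.ndarray:
    return np.asarray(t)[in_intervals(t, intervals)]


def sample_mask(n_samples: int, fs: float, intervals) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    for s, e, *_ in intervals:
        i0 = max(int(np.ceil(s * fs)), 0)
        i1 = min(int(np.ceil(e * fs)), n_samples)
        if i1 > i0:
            mask[i0:i1] = True
    return mask


def complement_intervals(intervals, start: float, end: float):
    """Gaps between sorted disjoint intervals within [start, end)."""
    out = []
    cur = start
    for s, e, *_ in sorted(intervals):
        if s > cur:
            out.append((cur, min(s, end)))
        cur = max(cur, e)
    if cur < end:
        out.append((cur, end))
    return out


def merge_intervals(intervals, gap: float = 0.0):
    """Union of intervals, merging any separated by ≤ gap."""
    ivs = sorted((float(s), float(e)) for s, e, *_ in intervals)
    out: list[list[float]] = []
    for s, e in ivs:
        if out and s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect_intervals(a, b):
    """Pairwise intersection of two sorted disjoint interval lists."""
    out = []
    i = j = 0
    a = sorted((s, e) for s, e, *_ in a)
    b = sorted((s, e) for s, e, *_ in b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


# --------------------------------------------------------------------------
# windowed FFT frames


def welch_frames(x: np.ndarray, fs: float, nperseg: int, noverlap: int,
                 window: str = "hann"):
    """Windowed one-sided FFT of overlapping frames.

    Returns (freqs, frame_center_times, Z) with Z shaped
    (..., n_freqs, n_frames); Z is scaled so that |Z|^2 averages to the
    one-sided PSD up to a constant factor common to all entries.
    """
    x = np.asarray(x, dtype=float)
    step = nperseg - noverlap
    n = x.shape[-1]
    n_frames = max((n - nperseg) // step + 1, 0)
    if n_frames == 0:
        raise ValueError("signal shorter than one frame")
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_frames)[:, None]
    frames = x[..., idx]                      # (..., n_frames, nperseg)
    win = signal.get_window(window, nperseg)
    frames = frames - frames.mean(axis=-1, keepdims=True)
    Z = np.fft.rfft(frames * win, axis=-1)
    Z = np.moveaxis(Z, -1, -2)                # (..., n_freqs, n_frames)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    t = (np.arange(n_frames) * step + nperseg / 2) / fs
    return freqs, t, Z


# --------------------------------------------------------------------------
# seeding


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(seed)
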