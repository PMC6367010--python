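"""Brain-state scoring (WAKE / NREM / REM) and slow-wave (DOWN/UP)
detection.

Scoring uses three per-second traces computed from the LFP: the first
principal component of the z-scored log-spectrogram (dominated by
low-frequency power, high during NREM), a theta-dominance ratio
(5-10 Hz / 2-16 Hz power, high during REM), and an EMG proxy (zero-lag
correlation of 300-600 Hz filtered signals across sites, high during
waking when muscle activity is volume-conducted into the brain).
Divisions are made at the trough between the two largest modes of each
trace's distribution; waking bouts shorter than 7 minutes are merged into
the surrounding sleep.

DOWN states are detected as the coincidence of a delta-band (0.5-8 Hz)
peak and a drop in high-frequency (100-400 Hz) power, with adaptive
thresholds calibrated against population spiking and a 40 ms minimum
duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import gaussian_kde

from ._utils import (bandpass, complement_intervals, intersect_intervals,
                     merge_intervals, sample_mask, smooth_boxcar, welch_frames)

STATE_LABELS = ("WAKE", "NREM", "REM")


@dataclass
class ScoringTraces:
    """Per-1-s-frame scoring metrics (aligned to frame centers)."""

    frame_times: np.ndarray
    pc1: np.ndarray
    theta_ratio: np.ndarray
    emg_proxy: np.ndarray


@dataclass
class StateSegmentation:
    intervals: list                     # (start, end, label)
    frame_times: np.ndarray
    frame_labels: np.ndarray
    traces: ScoringTraces | None = None
    merged_arousals: list = field(default_factory=list)

    def intervals_of(self, label: str) -> list:
        return [(s, e) for s, e, lab in self.intervals if lab == label]


@dataclass
class DownUpEvents:
    down: list                          # (start, end)
    up: list                            # (start, end)
    delta_peak_sd: np.ndarray           # per DOWN event
    gamma_min: np.ndarray               # per DOWN event
    thresholds: dict = field(default_factory=dict)

    @property
    def n_down(self) -> int:
        return len(self.down)


# --------------------------------------------------------------------------
# scoring traces


def compute_scoring_traces(rec, channel: int | None = None,
                           window_s: float = 10.0, step_s: float = 1.0,
                           emg_channels: int = 8) -> ScoringTraces:
    """Spectrogram-derived state-scoring metrics.

    One frame per second, 10 s centered windows (edge frames truncated),
    log-spaced 1-100 Hz spectrogram of a single representative channel
    (default: 55% depth, near the mid-layer-5 firing maximum).  PC1 of the
    z-scored log spectrogram is sign-oriented so that frames with high
    low-frequency (< 20 Hz) power are positive.
    """
    if rec.duration_s < 20:
        raise ValueError("session too short to score (< 20 s)")
    if rec.n_channels < 2:
        raise ValueError("EMG proxy needs >= 2 channels")
    fs = rec.fs
    if channel is None:
        channel = int(0.55 * (rec.n_channels - 1))
    x = rec.voltage_uv(channels=channel)

    n_frames = int(rec.duration_s // step_s)
    centers = (np.arange(n_frames) + 0.5) * step_s
    half = window_s / 2
    log_freqs = np.geomspace(1.0, 100.0, 100)

    nper = int(fs)  # 1 s FFT sub-windows averaged within the 10 s frame
    spec = np.empty((n_frames, log_freqs.size))
    freqs_lin = np.fft.rfftfreq(nper, 1 / fs)
    for i, c in enumerate(centers):
        i0 = max(int((c - half) * fs), 0)
        i1 = min(int((c + half) * fs), x.size)
        seg = x[i0:i1]
        n_sub = max(seg.size // nper, 1)
        seg = seg[: n_sub * nper].reshape(n_sub, -1)
        seg = seg - seg.mean(axis=1, keepdims=True)
        P = np.mean(np.abs(np.fft.rfft(seg * np.hanning(seg.shape[1]), axis=1)) ** 2,
                    axis=0)
        spec[i] = np.interp(log_freqs, freqs_lin[: P.size], P)

    logspec = np.log10(np.maximum(spec, 1e-300))
    z = (logspec - logspec.mean(0)) / np.maximum(logspec.std(0), 1e-12)
    # PC1 via SVD of the frame x frequency matrix
    u, s, vt = np.linalg.svd(z - z.mean(0), full_matrices=False)
    pc1 = u[:, 0] * s[0]
    if vt[0][log_freqs < 20].sum() < 0:
        pc1 = -pc1

    low = (log_freqs >= 2) & (log_freqs <= 16)
    mid = (log_freqs >= 5) & (log_freqs <= 10)
    theta_ratio = spec[:, mid].sum(1) / np.maximum(spec[:, low].sum(1), 1e-300)

    emg = _emg_proxy(rec, centers, step_s, emg_channels)
    return ScoringTraces(centers, pc1, theta_ratio, emg)


def _emg_proxy(rec, centers, step_s, emg_channels):
    """Mean zero-lag pairwise correlation of 300-600 Hz signals per frame."""
    fs = rec.fs
    picks = np.unique(np.linspace(0, rec.n_channels - 1,
                                  min(emg_channels, rec.n_channels)).astype(int))
    hf = bandpass(rec.voltage_uv(channels=picks), fs, 300.0,
                  min(600.0, 0.95 * fs / 2), order=4)
    out = np.empty(centers.size)
    half = step_s / 2
    iu = np.triu_indices(picks.size, 1)
    for i, c in enumerate(centers):
        i0 = max(int((c - half) * fs), 0)
        i1 = min(int((c + half) * fs), hf.shape[1])
        seg = hf[:, i0:i1]
        sd = seg.std(axis=1)
        if np.any(sd < 1e-12):
            out[i] = 0.0
            continue
        cc = np.corrcoef(seg)
        out[i] = float(cc[iu].mean())
    return out


# --------------------------------------------------------------------------
# histogram dip thresholds


def bimodal_dip(x: np.ndarray, grid_n: int = 512, max_dip_ratio: float = 0.5):
    """Trough between the two largest modes of a kernel density estimate.

    Returns (threshold, bimodal?) — ``bimodal=False`` when fewer than two
    clear modes exist, or when the trough is shallow (density above
    ``max_dip_ratio`` of the smaller peak), in which case the threshold is
    None.  The depth requirement keeps continuous within-state variation
    (e.g. oscillation bouts inside waking) from being split into states.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 or np.ptp(x) < 1e-12:
        return None, False
    kde = gaussian_kde(x)  # Silverman-type bandwidth
    grid = np.linspace(x.min(), x.max(), grid_n)
    dens = kde(grid)
    # zero-pad so modes at the range edges still count as peaks
    padded = np.concatenate([[0.0], dens, [0.0]])
    peaks, props = sp_signal.find_peaks(padded, prominence=0.05 * dens.max())
    peaks = peaks - 1
    if peaks.size < 2:
        return None, False
    order = np.argsort(props["prominences"])[::-1]
    p1, p2 = sorted(np.clip(peaks[order[:2]], 0, grid_n - 1))
    dip = p1 + int(np.argmin(dens[p1:p2 + 1]))
    if dens[dip] > max_dip_ratio * min(dens[p1], dens[p2]):
        return None, False
    return float(grid[dip]), True


# --------------------------------------------------------------------------
# state scoring


def score_states(traces: ScoringTraces, min_wake_s: float = 420.0,
                 step_s: float = 1.0,
                 fixed_pc1_threshold: float | None = None,
                 fixed_theta_threshold: float | None = None,
                 fixed_emg_threshold: float | None = None) -> StateSegmentation:
    """Divide frames into WAKE / NREM / REM.

    NREM = frames above the dip in the PC1 (broadband) distribution; among
    the rest, REM = low EMG and high theta (both relative to their own
    dips); everything else is WAKE.  Waking bouts shorter than
    ``min_wake_s`` (7 min) are merged into the surrounding sleep and
    reported in ``merged_arousals``.  When a trace's distribution is
    unimodal no division is made on it unless a fixed threshold is
    configured (a warning is emitted).
    """
    n = traces.pc1.size
    if n * step_s < 600:
        raise ValueError("need >= 10 min of frames to score states")

    pc1_thr, ok = bimodal_dip(traces.pc1)
    if not ok:
        pc1_thr = fixed_pc1_threshold
        warnings.warn("PC1 distribution not bimodal; "
                      + ("using configured fixed threshold" if pc1_thr is not None
                         else "no NREM division made"))
    labels = np.array(["WAKE"] * n, dtype=object)
    nrem_mask = traces.pc1 > pc1_thr if pc1_thr is not None else np.zeros(n, bool)
    labels[nrem_mask] = "NREM"

    rest = ~nrem_mask
    emg_thr, ok_e = bimodal_dip(traces.emg_proxy[rest]) if rest.sum() > 20 else (None, False)
    th_thr, ok_t = bimodal_dip(traces.theta_ratio[rest]) if rest.sum() > 20 else (None, False)
    if not ok_e:
        emg_thr = fixed_emg_threshold
    if not ok_t:
        th_thr = fixed_theta_threshold
    if emg_thr is not None and th_thr is not None:
        rem_mask = rest & (traces.emg_proxy < emg_thr) & (traces.theta_ratio > th_thr)
        labels[rem_mask] = "REM"

    labels = _median_smooth_labels(labels, 5)
    intervals = _labels_to_intervals(labels, traces.frame_times, step_s)
    intervals, merged = _enforce_min_wake(intervals, min_wake_s)

    frame_labels = labels.copy()
    for s, e, lab in intervals:
        sel = (traces.frame_times >= s) & (traces.frame_times < e)
        frame_labels[sel] = lab
    return StateSegmentation(intervals, traces.frame_times, frame_labels,
                             traces, merged)


def _median_smooth_labels(labels, k):
    codes = {"WAKE": 0, "NREM": 1, "REM": 2}
    inv = {v: k_ for k_, v in codes.items()}
    x = np.array([codes[l] for l in labels])
    half = k // 2
    out = x.copy()
    for i in range(x.size):
        seg = x[max(i - half, 0): i + half + 1]
        vals, cnt = np.unique(seg, return_counts=True)
        out[i] = vals[np.argmax(cnt)]
    return np.array([inv[v] for v in out], dtype=object)


def _labels_to_intervals(labels, frame_times, step_s):
    intervals = []
    start = frame_times[0] - step_s / 2
    cur = labels[0]
    for i in range(1, labels.size):
        if labels[i] != cur:
            end = frame_times[i] - step_s / 2
            intervals.append((start, end, cur))
            start, cur = end, labels[i]
    intervals.append((start, frame_times[-1] + step_s / 2, cur))
    return intervals


def _enforce_min_wake(intervals, min_wake_s):
    """Merge sub-threshold WAKE bouts into the surrounding sleep."""
    merged_log = []
    out = list(intervals)
    changed = True
    while changed:
        changed = False
        for i, (s, e, lab) in enumerate(out):
            if lab != "WAKE" or (e - s) >= min_wake_s:
                continue
            prev_lab = out[i - 1][2] if i > 0 else None
            next_lab = out[i + 1][2] if i + 1 < len(out) else None
            target = None
            if prev_lab in ("NREM", "REM") and next_lab in ("NREM", "REM"):
                prev_dur = out[i - 1][1] - out[i - 1][0]
                next_dur = out[i + 1][1] - out[i + 1][0]
                target = prev_lab if prev_dur >= next_dur else next_lab
            elif prev_lab in ("NREM", "REM"):
                target = prev_lab
            elif next_lab in ("NREM", "REM"):
                target = next_lab
            if target is None:
                continue
            merged_log.append((s, e, target))
            out[i] = (s, e, target)
            changed = True
            break
        # coalesce adjacent equal labels
        out2 = []
        for iv in out:
            if out2 and out2[-1][2] == iv[2]:
                out2[-1] = (out2[-1][0], iv[1], iv[2])
            else:
                out2.append(iv)
        out = out2
    return out, merged_log


# --------------------------------------------------------------------------
# slow-wave (DOWN/UP) detection


def detect_slow_waves(rec, spikes, nrem_intervals, channel: int | None = None,
                      rate_criterion: float = 0.2,
                      candidate_sd: float = 0.25,
                      min_duration_s: float = 0.040,
                      max_duration_s: float = 1.0,
                      smooth_s: float = 0.080) -> DownUpEvents:
    """Detect DOWN states as coincident delta peaks and high-frequency
    power drops, with spiking-calibrated adaptive thresholds.

    For each of the two detection signals, candidate excursions beyond
    ``candidate_sd`` SD are binned by magnitude; the peak threshold is the
    smallest magnitude bin whose population-spike rate at the excursion
    peak falls below ``rate_criterion`` x the mean rate, and the window
    threshold (event boundaries) is the average signal value at which the
    rate recovers across qualifying bins.  DOWN events are overlapping
    delta and gamma-drop events of at least ``min_duration_s``.
    """
    total_nrem = sum(e - s for s, e in nrem_intervals)
    if total_nrem < 60:
        raise ValueError("need >= 60 s of NREM to detect slow waves")
    fs = rec.fs
    if channel is None:
        channel = int(0.55 * (rec.n_channels - 1))
    x = rec.voltage_uv(channels=channel)
    nrem_mask = sample_mask(x.size, fs, nrem_intervals)

    delta = bandpass(x, fs, 0.5, 8.0, order=4)
    hf = bandpass(x, fs, 100.0, min(400.0, 0.95 * fs / 2), order=4)
    gpow = smooth_boxcar(hf ** 2, int(smooth_s * fs))
    gpow = np.log10(np.maximum(gpow, 1e-300))

    delta_z = _z_within(delta, nrem_mask)
    gamma_z = _z_within(gpow, nrem_mask)

    pop_spikes = np.sort(np.concatenate([t for t in spikes.spike_times.values()])) \
        if spikes.spike_times else np.empty(0)

    delta_events, d_thr = _adaptive_events(
        delta_z, fs, nrem_mask, pop_spikes, rate_criterion, candidate_sd,
        drop=False)
    gamma_events, g_thr = _adaptive_events(
        -gamma_z, fs, nrem_mask, pop_spikes, rate_criterion, candidate_sd,
        drop=True)

    delta_events = [iv for iv in delta_events
                    if min_duration_s <= iv[1] - iv[0]]
    gamma_events = [iv for iv in gamma_events
                    if min_duration_s <= iv[1] - iv[0]]
    down = [iv for iv in intersect_intervals(delta_events, gamma_events)
            if min_duration_s <= iv[1] - iv[0] <= max_duration_s]
    down = merge_intervals(down, gap=0.0)

    peaks = np.empty(len(down))
    gmins = np.empty(len(down))
    for i, (s, e) in enumerate(down):
        i0, i1 = int(s * fs), int(e * fs)
        peaks[i] = delta_z[i0:i1].max() if i1 > i0 else np.nan
        gmins[i] = gamma_z[i0:i1].min() if i1 > i0 else np.nan

    up = []
    for s, e in nrem_intervals:
        inside = [iv for iv in down if iv[0] >= s and iv[1] <= e]
        up.extend(complement_intervals(inside, s, e))
    return DownUpEvents(down, up, peaks, gmins,
                        thresholds={"delta": d_thr, "gamma": g_thr})


def _z_within(x, mask):
    mu = x[mask].mean()
    sd = max(x[mask].std(), 1e-12)
    return (x - mu) / sd


def _adaptive_events(z, fs, nrem_mask, pop_spikes, rate_criterion,
                     candidate_sd, drop, bin_width_sd: float = 0.25,
                     min_per_bin: int = 5,
                     peth_halfwidth_s: float = 0.5, peth_bin_s: float = 0.02):
    """Candidate peaks of z binned by magnitude; spike-PETH calibration of
    the peak threshold; boundaries at window-threshold crossings.

    ``z`` must be oriented so excursions of interest are positive (the
    gamma-drop signal is passed negated).  Magnitude bins are fixed-width
    (``bin_width_sd`` SD) so sparse noise peaks and dense true events do
    not share a bin; the peak threshold is the lower edge of the smallest
    qualifying bin whose peri-peak population rate is below the criterion.
    The window threshold (event boundaries) comes from the signal value at
    the rate-recovery time, capped at half the peak threshold so that
    boundary crossings of the smoothed signal align with the true edge
    rather than sitting inside the event.
    """
    zm = z.copy()
    zm[~nrem_mask] = -np.inf
    pk_idx, _ = sp_signal.find_peaks(zm, height=candidate_sd)
    if pk_idx.size == 0:
        return [], {"peak": None, "window": None}
    mags = z[pk_idx]
    edges = np.arange(candidate_sd, mags.max() + bin_width_sd, bin_width_sd)
    mean_rate = pop_spikes.size / max(nrem_mask.sum() / fs, 1e-9)

    peak_thr = None
    crossing_vals = []
    if pop_spikes.size == 0 or mean_rate == 0:
        peak_thr = float(np.quantile(mags, 0.5))
    else:
        nb = int(2 * peth_halfwidth_s / peth_bin_s)
        for b in range(edges.size - 1):
            sel = (mags >= edges[b]) & (mags < edges[b + 1])
            if sel.sum() < min_per_bin:
                continue
            centers_t = pk_idx[sel] / fs
            peth = np.zeros(nb)
            for t0 in centers_t:
                rel = pop_spikes[np.searchsorted(pop_spikes, t0 - peth_halfwidth_s):
                                 np.searchsorted(pop_spikes, t0 + peth_halfwidth_s)] - t0
                hist, _ = np.histogram(rel, bins=nb,
                                       range=(-peth_halfwidth_s, peth_halfwidth_s))
                peth += hist
            peth = peth / (sel.sum() * peth_bin_s)      # Hz
            norm = peth / max(peth.mean(), 1e-12)
            center_bin = nb // 2
            if norm[center_bin] < rate_criterion:
                if peak_thr is None:
                    peak_thr = float(edges[b])
                # signal value where the rate recovers above criterion
                above = np.flatnonzero(norm > rate_criterion)
                left = above[above < center_bin]
                right = above[above > center_bin]
                for edge_bin in ([left.max()] if left.size else []) + \
                                ([right.min()] if right.size else []):
                    dt = (edge_bin - center_bin + 0.5) * peth_bin_s
                    vals = [z[int((t0 + dt) * fs)] for t0 in centers_t
                            if 0 <= int((t0 + dt) * fs) < z.size]
                    if vals:
                        crossing_vals.append(np.mean(vals))
        if peak_thr is None:
            return [], {"peak": None, "window": None}
    window_thr = float(np.mean(crossing_vals)) if crossing_vals \
        else max(candidate_sd, 0.5 * peak_thr)
    window_thr = min(window_thr, 0.5 * peak_thr)
    window_thr = max(window_thr, 0.0)

    events = []
    above = z >= window_thr
    for i0 in pk_idx[z[pk_idx] >= peak_thr]:
        j0 = i0
        while j0 > 0 and above[j0 - 1]:
            j0 -= 1
        j1 = i0
        while j1 < z.size - 1 and above[j1 + 1]:
            j1 += 1
        events.append((j0 / fs, (j1 + 1) / fs))
    return merge_intervals(events), {"peak": peak_thr, "window": window_thr}
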