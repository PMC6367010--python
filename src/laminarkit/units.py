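"""Unit classification and per-unit physiological statistics.

Classification proceeds in stages: waveform shape (trough-to-peak latency
with a 0.55 ms narrow/wide boundary, positive-polarity units, and fiber
volleys flagged by an outlying second-derivative kurtosis), short-latency
cross-correlogram identity (delegated to ``connectivity``), optogenetic
tagging (light-evoked short-latency rate exceeding baseline by 8 SD), and
clustering of spike - gamma-IC phase-coupling profiles (cityblock k-means
with the silhouette criterion).

Per-unit statistics: burst index (autocorrelogram 1.5-13.5 ms vs
200-300 ms), transient/steady UP-state ratio, first-spike latency after
DOWN->UP transitions, per-state firing rates, and DOWN-state-active
detection by per-event rank-sum comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import in_intervals

__all__ = [
    "classify_waveform",
    "classify_units",
    "tp_latency_ms",
    "optotag",
    "burst_index",
    "acg",
    "up_state_dynamics",
    "detect_down_active",
    "DownActiveResult",
    "cluster_by_ic_coupling",
    "CouplingClusters",
    "state_rate_table",
]

TP_BOUNDARY_MS = 0.55


# --------------------------------------------------------------------------
# waveform classification


def tp_latency_ms(mean_waveform: np.ndarray, fs: float) -> float:
    """Trough-to-peak latency of a negative-going extracellular waveform."""
    wf = np.asarray(mean_waveform, dtype=float)
    trough = int(np.argmin(wf))
    after = wf[trough:]
    if after.size < 2:
        raise ValueError("trough at waveform end; cannot measure peak")
    peak = trough + int(np.argmax(after))
    return (peak - trough) / fs * 1e3


def classify_waveform(mean_waveform: np.ndarray, fs: float):
    """Single-waveform classification: POSITIVE / E / I with TP latency.

    POSITIVE if the extreme value is positive; otherwise E for
    trough-to-peak latency > 0.55 ms, I for <= 0.55 ms.  (Fiber-volley
    flagging needs the population; see ``classify_units``.)  The decision
    is scale-invariant.
    """
    wf = np.asarray(mean_waveform, dtype=float)
    if fs < 10000:
        raise ValueError("waveform sampling rate must be >= 10 kHz")
    if wf.size < 32:
        raise ValueError("waveform too short (need >= 32 samples)")
    if np.ptp(wf) < 1e-12:
        raise ValueError("flat waveform cannot be classified")
    if wf[np.argmax(np.abs(wf))] > 0:
        return "POSITIVE", np.nan
    tp = tp_latency_ms(wf, fs)
    return ("E" if tp > TP_BOUNDARY_MS else "I"), tp


def _second_derivative_kurtosis(wf: np.ndarray) -> float:
    w = wf / np.max(np.abs(wf))
    return float(stats.kurtosis(np.diff(w, n=2)))


def classify_units(waveforms: dict, fs: float, robust: bool = False,
                   fiber_sd: float = 5.0) -> pd.DataFrame:
    """Population waveform classification (adds the FIBER class).

    Fiber volleys are negative-waveform units whose normalized-waveform
    second-derivative kurtosis is an outlier beyond ``fiber_sd`` on the
    population scale (mean/SD by default).  ``robust=True`` switches to a
    median/MAD z-score; note that on a healthy population the kurtosis
    distribution is bimodal (narrow vs wide waveforms), which makes the
    MAD scale collapse and mislabel ordinary narrow waveforms, so the
    literal rule is the default.
    """
    rows = []
    for uid, wf in waveforms.items():
        cls, tp = classify_waveform(wf, fs)
        kurt = np.nan if cls == "POSITIVE" else _second_derivative_kurtosis(np.asarray(wf, float))
        rows.append((uid, cls, tp, kurt))
    df = pd.DataFrame(rows, columns=["unit_id", "waveform_class",
                                     "tp_latency_ms", "d2_kurtosis"])
    neg = df.waveform_class != "POSITIVE"
    k = df.loc[neg, "d2_kurtosis"].to_numpy()
    if neg.sum() >= 5:
        if robust:
            center = np.median(k)
            scale = 1.4826 * np.median(np.abs(k - center))
        else:
            center, scale = np.mean(k), np.std(k)
        if scale > 1e-12:
            z = (k - center) / scale
            fiber = np.abs(z) > fiber_sd
            df.loc[df.index[neg][fiber], "waveform_class"] = "FIBER"
    return df.set_index("unit_id")


# --------------------------------------------------------------------------
# optotagging


def optotag(spike_times: np.ndarray, pulse_times: np.ndarray,
            bin_ms: float = 1.0, window_ms=(1.0, 6.0),
            baseline_ms=(-100.0, 0.0), sd_criterion: float = 8.0):
    """Light-pulse response test.

    Tagged iff the mean of the two largest 1 ms bins in the 1-6 ms
    post-pulse window exceeds baseline mean + ``sd_criterion`` x baseline
    SD (computed over the -100..0 ms bins).  Returns
    ``(tagged, peak_rate_hz, baseline_mean_hz, baseline_sd_hz, degenerate)``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size < 100:
        raise ValueError("need >= 100 light pulses")
    b = bin_ms * 1e-3
    lo, hi = baseline_ms[0] * 1e-3, window_ms[1] * 1e-3
    edges = np.arange(lo, hi + b / 2, b)
    counts = np.zeros(edges.size - 1)
    for t0 in pulse_times:
        rel = spike_times[np.searchsorted(spike_times, t0 + lo):
                          np.searchsorted(spike_times, t0 + hi)] - t0
        c, _ = np.histogram(rel, bins=edges)
        counts += c
    rate = counts / (pulse_times.size * b)      # Hz per bin
    centers = (edges[:-1] + edges[1:]) / 2
    base = rate[(centers >= baseline_ms[0] * 1e-3) & (centers < baseline_ms[1] * 1e-3)]
    resp = rate[(centers >= window_ms[0] * 1e-3) & (centers < window_ms[1] * 1e-3)]
    if resp.size < 2:
        raise ValueError("response window narrower than two bins")
    peak = float(np.mean(np.sort(resp)[-2:]))   # mean of two largest bins
    mu, sd = float(base.mean()), float(base.std())
    if sd == 0.0:
        # silent baseline: any response spikes count, flagged degenerate
        return peak > 0, peak, mu, sd, True
    return peak > mu + sd_criterion * sd, peak, mu, sd, False


# --------------------------------------------------------------------------
# autocorrelogram / burstiness


def acg(spike_times: np.ndarray, bin_ms: float = 0.5,
        halfwidth_ms: float = 300.0):
    """One-sided autocorrelogram (positive lags, zero-lag excluded)."""
    t = np.asarray(spike_times, dtype=float)
    hw = halfwidth_ms * 1e-3
    edges = np.arange(0.0, hw + bin_ms * 1e-3 / 2, bin_ms * 1e-3)
    starts = np.arange(t.size) + 1
    hi = np.searchsorted(t, t + hw, side="right")
    m = np.maximum(hi - starts, 0)
    total = int(m.sum())
    if total:
        idx = np.repeat(np.arange(t.size), m)
        flat = np.arange(total) - np.repeat(np.cumsum(m) - m, m) + np.repeat(starts, m)
        counts, _ = np.histogram(t[flat] - t[idx], bins=edges)
    else:
        counts = np.zeros(edges.size - 1)
    lags_ms = (edges[:-1] + edges[1:]) / 2 * 1e3
    return lags_ms, counts.astype(float)


def burst_index(spike_times: np.ndarray, numerator_ms=(1.5, 13.5),
                denominator_ms=(200.0, 300.0), bin_ms: float = 0.5):
    """Bursting propensity: mean autocorrelogram count in the short-latency
    window divided by the mean count at 200-300 ms.

    ~1 for a Poisson train (flat autocorrelogram), ~0 for a refractory
    regular train, > 1 for bursty units.  Returns NaN (flagged) when the
    baseline window is empty.  The short window defaults to 1.5-13.5 ms;
    pass ``numerator_ms=(3, 10)`` for the coarser variant.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 100:
        raise ValueError("need >= 100 spikes for a stable burst index")
    lags, counts = acg(t, bin_ms=bin_ms, halfwidth_ms=denominator_ms[1])
    num = counts[(lags >= numerator_ms[0]) & (lags < numerator_ms[1])]
    den = counts[(lags >= denominator_ms[0]) & (lags < denominator_ms[1])]
    if den.mean() == 0:
        warnings.warn("empty baseline autocorrelogram window; burst index undefined")
        return np.nan
    return float(num.mean() / den.mean())


# --------------------------------------------------------------------------
# UP-state dynamics


def up_state_dynamics(spike_times: np.ndarray, up_onsets: np.ndarray,
                      peak_window_s=(0.0, 0.2), steady_window_s=(0.1, 0.2),
                      bin_s: float = 0.01, latency_censor_s: float = 0.5):
    """Transient/steady firing ratio and DOWN->UP first-spike latency.

    The peri-onset histogram (10 ms bins) gives ratio = max rate in
    0-200 ms / mean rate in 100-200 ms; latency is the median first-spike
    time (transitions with no spike within ``latency_censor_s`` excluded).
    Returns ``(ratio, latency_s)``; ratio is NaN (flagged) for a silent
    steady window.
    """
    t = np.asarray(spike_times, dtype=float)
    onsets = np.asarray(up_onsets, dtype=float)
    if onsets.size < 50:
        raise ValueError("need >= 50 UP-state onsets")
    edges = np.arange(peak_window_s[0], peak_window_s[1] + bin_s / 2, bin_s)
    counts = np.zeros(edges.size - 1)
    first = []
    for t0 in onsets:
        rel = t[np.searchsorted(t, t0 + peak_window_s[0]):
                np.searchsorted(t, t0 + max(peak_window_s[1], latency_censor_s))] - t0
        c, _ = np.histogram(rel, bins=edges)
        counts += c
        after = rel[rel >= 0]
        if after.size and after[0] <= latency_censor_s:
            first.append(after[0])
    rate = counts / (onsets.size * bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    steady = rate[(centers >= steady_window_s[0]) & (centers < steady_window_s[1])]
    if steady.mean() == 0:
        warnings.warn("zero steady-state rate; transient/steady ratio undefined")
        ratio = np.nan
    else:
        ratio = float(rate.max() / steady.mean())
    latency = float(np.median(first)) if first else np.nan
    return ratio, latency


# --------------------------------------------------------------------------
# DOWN-state-active detection


@dataclass
class DownActiveResult:
    unit_id: int
    rate_down_hz: float
    rate_up_hz: float
    p_value: float
    flagged: bool


def detect_down_active(spike_times: np.ndarray, down_intervals, up_intervals,
                       alpha: float = 0.05, unit_id: int = -1) -> DownActiveResult:
    """Flag units firing predominantly during DOWN states.

    Per-event rates in DOWN vs UP epochs are compared with a Wilcoxon
    rank-sum test; a unit is flagged iff its median DOWN rate exceeds the
    median UP rate and p < alpha.
    """
    if len(down_intervals) < 50 or len(up_intervals) < 50:
        raise ValueError("need >= 50 DOWN and >= 50 UP events")
    t = np.asarray(spike_times, dtype=float)

    def per_event_rates(intervals):
        out = np.empty(len(intervals))
        for i, (s, e) in enumerate(intervals):
            n = np.searchsorted(t, e) - np.searchsorted(t, s)
            out[i] = n / max(e - s, 1e-9)
        return out

    rd = per_event_rates(down_intervals)
    ru = per_event_rates(up_intervals)
    if t.size == 0 or (rd.sum() == 0 and ru.sum() == 0):
        return DownActiveResult(unit_id, 0.0, 0.0, 1.0, False)
    stat, p = stats.ranksums(rd, ru)
    flagged = bool(np.median(rd) > np.median(ru) and p < alpha)
    return DownActiveResult(unit_id, float(rd.mean()), float(ru.mean()),
                            float(p), flagged)


# --------------------------------------------------------------------------
# spike - gamma-IC coupling clusters


@dataclass
class CouplingClusters:
    assignment: np.ndarray        # per-unit cluster id, 0..K-1
    k: int
    silhouette: float
    per_unit_silhouette: np.ndarray
    centers: np.ndarray
    degenerate: bool = False
    k_scores: dict = field(default_factory=dict)


def _kmedians(X, k, rng, n_init=10, max_iter=100):
    """Lloyd iterations with the cityblock metric (median center update)."""
    from scipy.spatial.distance import cdist

    best = None
    for _ in range(n_init):
        centers = X[rng.choice(X.shape[0], size=k, replace=False)].copy()
        labels = np.zeros(X.shape[0], dtype=int)
        for it in range(max_iter):
            D = cdist(X, centers, metric="cityblock")
            new_labels = np.argmin(D, axis=1)
            if it > 0 and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                pts = X[labels == j]
                if pts.size:
                    centers[j] = np.median(pts, axis=0)
                else:  # re-seed an empty cluster at the worst-fit point
                    centers[j] = X[np.argmax(D.min(axis=1))]
        cost = float(cdist(X, centers, metric="cityblock")[
            np.arange(X.shape[0]), labels].sum())
        if best is None or cost < best[0]:
            best = (cost, labels.copy(), centers.copy())
    return best[1], best[2]


def cluster_by_ic_coupling(R: np.ndarray, k_range=range(2, 13),
                           seed=None) -> CouplingClusters:
    """Cluster units by their spike - gamma-IC coupling profiles.

    ``R[unit, ic]`` holds the mean resultant length at the unit's
    preferred gamma frequency per IC (0 where the Rayleigh test is not
    significant).  Cityblock k-means is run over ``k_range`` and K chosen
    to maximize the mean silhouette (cityblock metric).  An (near-)
    identical-profile population is returned as a flagged single cluster.
    """
    from sklearn.metrics import silhouette_samples, silhouette_score

    X = np.asarray(R, dtype=float)
    if X.shape[0] < 20:
        raise ValueError("need >= 20 units with significant coupling")
    rng = np.random.default_rng(seed)
    if np.allclose(X, X[0], atol=1e-12):
        return CouplingClusters(np.zeros(X.shape[0], dtype=int), 1, np.nan,
                                np.full(X.shape[0], np.nan),
                                X[:1].copy(), degenerate=True)
    best = None
    scores = {}
    for k in k_range:
        if k >= X.shape[0]:
            break
        labels, centers = _kmedians(X, k, rng)
        if np.unique(labels).size < 2:
            continue
        score = float(silhouette_score(X, labels, metric="cityblock"))
        scores[k] = score
        if best is None or score > best[0]:
            best = (score, k, labels, centers)
    if best is None:
        return CouplingClusters(np.zeros(X.shape[0], dtype=int), 1, np.nan,
                                np.full(X.shape[0], np.nan), X[:1].copy(),
                                degenerate=True)
    score, k, labels, centers = best
    per_unit = silhouette_samples(X, labels, metric="cityblock")
    return CouplingClusters(labels, k, score, per_unit, centers,
                            k_scores=scores)


# --------------------------------------------------------------------------
# per-state rates


def state_rate_table(spike_times: np.ndarray, state_intervals,
                     min_state_s: float = 60.0) -> pd.DataFrame:
    """Firing rate per brain state plus the wake/non-REM ratio.

    Rate = spike count within the state's intervals / total state
    duration.  The ratio is NaN when either state is missing (< 60 s) and
    +inf when the unit is silent in non-REM but not waking.
    """
    t = np.asarray(spike_times, dtype=float)
    labels = sorted({lab for _, _, lab in state_intervals})
    rows = []
    for lab in labels:
        ivs = [(s, e) for s, e, l in state_intervals if l == lab]
        dur = sum(e - s for s, e in ivs)
        n = int(in_intervals(t, ivs).sum())
        rows.append((lab, dur, n, n / dur if dur > 0 else np.nan))
    df = pd.DataFrame(rows, columns=["state", "duration_s", "n_spikes",
                                     "rate_hz"]).set_index("state")
    ratio = np.nan
    if ("WAKE" in df.index and "NREM" in df.index
            and df.loc["WAKE", "duration_s"] >= min_state_s
            and df.loc["NREM", "duration_s"] >= min_state_s):
        rw, rn = df.loc["WAKE", "rate_hz"], df.loc["NREM", "rate_hz"]
        ratio = np.inf if rn == 0 and rw > 0 else (rw / rn if rn > 0 else np.nan)
    df.attrs["wake_nrem_ratio"] = float(ratio) if np.isfinite(ratio) else ratio
    return df
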