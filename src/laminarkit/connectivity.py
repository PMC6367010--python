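"""Monosynaptic connectivity from spike-train cross-correlograms (CCGs).

A putative connection appears as a short-latency (1.5-4 ms) peak
(excitatory) or trough (inhibitory) in the 0.5 ms-binned CCG relative to a
slow baseline predictor obtained by convolving the CCG with a 7 ms-SD
Gaussian.  Per-bin significance uses the exact Poisson tail at the
predicted rate (99.9999th percentile), and an edge requires at least two
consecutive significant bins inside the (+1.5, +4] ms window.  Spike
transmission probability is the summed excess count in that window per
presynaptic spike; the peak-to-baseline ratio is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import in_intervals

__all__ = [
    "Ccg",
    "Edge",
    "compute_ccg",
    "baseline_predictor",
    "poisson_bounds",
    "detect_edges",
    "transmission_probability",
    "state_dependent_transmission",
    "compare_state_transmission",
    "ccg_identity",
    "EDGE_WINDOW_MS",
]

#: detection window (+1.5, +4] ms; at 0.5 ms bins these are the five bins
#: centered 1.75 - 3.75 ms
EDGE_WINDOW_MS = (1.5, 4.0)
P_HI_DEFAULT = 0.999999


# --------------------------------------------------------------------------
# cross-correlogram


@dataclass
class Ccg:
    counts: np.ndarray          # integer counts per bin
    lags_ms: np.ndarray         # bin centers
    bin_ms: float
    n_pre: int
    n_post: int

    @property
    def halfwidth_ms(self) -> float:
        return float(self.lags_ms[-1] + self.bin_ms / 2)


def compute_ccg(pre_times, post_times, bin_ms: float = 0.5,
                halfwidth_ms: float = 50.0, intervals=None) -> Ccg:
    """Histogram of post-minus-pre spike lags within +-halfwidth.

    Both trains are restricted to ``intervals`` (list of half-open
    ``(start, end)``) when given, and pairs are counted per interval so
    lags never span interval boundaries.  When pre and post are the same
    train, identical-index (zero-lag self) pairs are excluded.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    same = pre.shape == post.shape and np.array_equal(pre, post)
    if intervals is None:
        intervals = [(-np.inf, np.inf)]
    hw = halfwidth_ms * 1e-3
    b = bin_ms * 1e-3
    # bin edges on the bin-width grid (..., -0.5, 0, +0.5, ... ms) so the
    # (+1.5, +4] ms window is exactly the five bins centered 1.75-3.75 ms
    half_bins = int(round(hw / b))
    n_bins = 2 * half_bins
    edges = (np.arange(n_bins + 1) - half_bins) * b
    counts = np.zeros(n_bins, dtype=np.int64)
    n_pre_tot = n_post_tot = 0
    for s, e, *_ in intervals:
        p = pre[(pre >= s) & (pre < e)]
        q = post[(post >= s) & (post < e)]
        n_pre_tot += p.size
        n_post_tot += q.size
        if p.size == 0 or q.size == 0:
            continue
        lo = np.searchsorted(q, p - hw, side="left")
        hi = np.searchsorted(q, p + hw, side="right")
        m = hi - lo
        total = int(m.sum())
        if total == 0:
            continue
        # vectorized enumeration of all (pre, post) index pairs in range
        idx = np.repeat(np.arange(p.size), m)
        flat = np.arange(total) - np.repeat(np.cumsum(m) - m, m) + np.repeat(lo, m)
        diffs = q[flat] - p[idx]
        c, _ = np.histogram(diffs, bins=edges)
        counts += c
    if n_pre_tot == 0 or n_post_tot == 0:
        raise ValueError("empty spike train within the analysis intervals")
    if same:
        counts[half_bins] -= n_pre_tot  # zero-lag self pairs land in [0, b)
    lags_ms = (edges[:-1] + edges[1:]) / 2 * 1e3
    return Ccg(counts, lags_ms, bin_ms, n_pre_tot, n_post_tot)


def baseline_predictor(ccg: Ccg, sigma_ms: float = 7.0,
                       hollow_window_ms=None) -> np.ndarray:
    """Slowly varying expected count per bin: the CCG convolved with a
    unit-area Gaussian (SD ``sigma_ms``), reflected at the edges.  The
    total count is preserved and the output is non-negative.

    With ``hollow_window_ms`` the bins inside that lag window are replaced
    by linear interpolation across it before convolving, so a monosynaptic
    peak does not inflate its own baseline.  Detection uses the plain
    predictor; transmission estimation uses the hollowed one.
    """
    from scipy.ndimage import gaussian_filter1d

    counts = ccg.counts.astype(float)
    if hollow_window_ms is not None:
        w = np.flatnonzero((ccg.lags_ms > hollow_window_ms[0])
                           & (ccg.lags_ms <= hollow_window_ms[1]))
        if w.size and w[0] > 0 and w[-1] < counts.size - 1:
            counts = counts.copy()
            lo, hi = w[0] - 1, w[-1] + 1
            counts[w] = np.interp(w, [lo, hi], [counts[lo], counts[hi]])
    sigma_bins = sigma_ms / ccg.bin_ms
    pred = gaussian_filter1d(counts, sigma_bins, mode="reflect")
    return np.maximum(pred, 0.0)


# --------------------------------------------------------------------------
# exact Poisson thresholds


def poisson_bounds(lam: float, p_hi: float = P_HI_DEFAULT) -> tuple[int, int]:
    """Exact two-sided Poisson count thresholds at rate ``lam``.

    ``k_hi`` is the smallest integer with CDF(k; lam) >= p_hi and ``k_lo``
    the largest integer with CDF(k; lam) <= 1 - p_hi (-1 if none), both
    from the exact cumulative distribution (no normal approximation).
    Counts strictly above ``k_hi`` / strictly below ``k_lo`` then have
    tail probability at most ``1 - p_hi`` under the predicted rate.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return 0, -1
    k = int(stats.poisson.ppf(p_hi, lam))  # smallest k with CDF >= p_hi
    while stats.poisson.cdf(k, lam) < p_hi:
        k += 1
    while k > 0 and stats.poisson.cdf(k - 1, lam) >= p_hi:
        k -= 1
    k_hi = k
    q = 1.0 - p_hi
    k2 = int(stats.poisson.ppf(q, lam))
    while k2 >= 0 and stats.poisson.cdf(k2, lam) > q:
        k2 -= 1
    return k_hi, int(k2)


# --------------------------------------------------------------------------
# edge detection


@dataclass
class Edge:
    pre: int
    post: int
    sign: str                   # "E" or "I"
    significant_lags_ms: np.ndarray
    transmission: dict = field(default_factory=dict)       # per state
    peak_to_baseline: dict = field(default_factory=dict)   # per state
    ambiguous: bool = False


def _window_mask(ccg: Ccg, window_ms=EDGE_WINDOW_MS) -> np.ndarray:
    # half-open (lo, hi]: bins whose centers lie strictly above lo and at
    # or below hi
    return (ccg.lags_ms > window_ms[0]) & (ccg.lags_ms <= window_ms[1])


def detect_edges(ccg: Ccg, predictor: np.ndarray, pre: int = -1, post: int = -1,
                 window_ms=EDGE_WINDOW_MS, p_hi: float = P_HI_DEFAULT,
                 min_consecutive: int = 2) -> list[Edge]:
    """Detect an excitatory and/or inhibitory edge in a CCG.

    Excitatory: >= ``min_consecutive`` consecutive window bins with count
    strictly above the upper Poisson bound of the predictor; inhibitory:
    analogous run strictly below the lower bound.  Both present -> both
    edges returned, flagged ambiguous.  Returns a list of 0-2 edges.
    """
    if predictor.shape != ccg.counts.shape:
        raise ValueError("predictor must align with CCG bins")
    wsel = np.flatnonzero(_window_mask(ccg, window_ms))
    hi_sig = np.zeros(wsel.size, dtype=bool)
    lo_sig = np.zeros(wsel.size, dtype=bool)
    for j, b in enumerate(wsel):
        k_hi, k_lo = poisson_bounds(predictor[b], p_hi)
        hi_sig[j] = ccg.counts[b] > k_hi
        lo_sig[j] = ccg.counts[b] < k_lo
    edges = []
    for sign, sig in (("E", hi_sig), ("I", lo_sig)):
        if _has_run(sig, min_consecutive):
            edges.append(Edge(pre, post, sign, ccg.lags_ms[wsel[sig]]))
    if len(edges) == 2:
        for e in edges:
            e.ambiguous = True
    return edges


def _has_run(mask: np.ndarray, k: int) -> bool:
    run = 0
    for m in mask:
        run = run + 1 if m else 0
        if run >= k:
            return True
    return False


# --------------------------------------------------------------------------
# spike transmission probability


def transmission_probability(ccg: Ccg, predictor: np.ndarray | None = None,
                             window_ms=EDGE_WINDOW_MS):
    """Excess postsynaptic spikes per presynaptic spike in the
    monosynaptic window, and the peak-to-baseline ratio.

    transmission = sum(count - predictor) over the window / n_pre
    (negative for inhibitory troughs); peak_to_baseline = max window count
    / mean window predictor.  Returns ``(transmission, peak_to_baseline)``.
    When no predictor is passed, the window-hollowed baseline predictor is
    used, which does not let the peak inflate its own baseline.
    """
    if ccg.n_pre == 0:
        raise ValueError("no presynaptic spikes")
    if predictor is None:
        predictor = baseline_predictor(ccg, hollow_window_ms=window_ms)
    w = _window_mask(ccg, window_ms)
    excess = float(np.sum(ccg.counts[w] - predictor[w]))
    p2b = float(ccg.counts[w].max() / max(predictor[w].mean(), 1e-300))
    return excess / ccg.n_pre, p2b


def state_dependent_transmission(pre_times, post_times, state_intervals,
                                 states=("WAKE", "NREM"),
                                 min_pre_spikes: int = 500,
                                 bin_ms: float = 0.5, halfwidth_ms: float = 50.0,
                                 sigma_ms: float = 7.0,
                                 window_ms=EDGE_WINDOW_MS) -> dict:
    """Per-state spike transmission for one pair.

    The CCG and its baseline predictor are recomputed within each state's
    intervals.  States contributing fewer than ``min_pre_spikes``
    presynaptic spikes are reported as None (excluded from comparisons).
    """
    out = {}
    pre = np.asarray(pre_times, dtype=float)
    for lab in states:
        ivs = [(s, e) for s, e, l in state_intervals if l == lab]
        n_pre = int(in_intervals(pre, ivs).sum()) if ivs else 0
        if n_pre < min_pre_spikes:
            out[lab] = None
            continue
        ccg = compute_ccg(pre, post_times, bin_ms, halfwidth_ms, intervals=ivs)
        p, p2b = transmission_probability(ccg, window_ms=window_ms)
        out[lab] = {"transmission": p, "peak_to_baseline": p2b,
                    "n_pre": n_pre}
    return out


def compare_state_transmission(per_edge_values, state_a="WAKE", state_b="NREM"):
    """Population comparison of paired per-edge transmission values.

    ``per_edge_values`` is a list of dicts as returned by
    ``state_dependent_transmission``; edges missing either state are
    dropped.  Returns ``(n_pairs, median_difference, signed_rank_p)``;
    refuses (ValueError) when fewer than two complete pairs exist.
    """
    a, b = [], []
    for d in per_edge_values:
        va, vb = d.get(state_a), d.get(state_b)
        if va is None or vb is None:
            continue
        a.append(va["transmission"])
        b.append(vb["transmission"])
    if len(a) < 2:
        raise ValueError("need >= 2 edges with both states present")
    a, b = np.asarray(a), np.asarray(b)
    diff = a - b
    if np.allclose(diff, 0):
        return len(a), 0.0, 1.0
    stat, p = stats.wilcoxon(a, b)
    return len(a), float(np.median(diff)), float(p)


# --------------------------------------------------------------------------
# CCG-based cell identity


def ccg_identity(edges: list[Edge]) -> dict[int, str]:
    """Per-unit identity from outgoing edges: E for >= 1 outgoing
    excitatory edge, I for >= 1 outgoing inhibitory edge, AMBIGUOUS when
    both kinds are present."""
    has_e: set[int] = set()
    has_i: set[int] = set()
    for e in edges:
        (has_e if e.sign == "E" else has_i).add(e.pre)
    out = {}
    for u in has_e | has_i:
        if u in has_e and u in has_i:
            out[u] = "AMBIGUOUS"
        else:
            out[u] = "E" if u in has_e else "I"
    return out


# --------------------------------------------------------------------------
# network scan


def detect_network_edges(spikes, intervals=None, bin_ms: float = 0.5,
                         halfwidth_ms: float = 50.0, sigma_ms: float = 7.0,
                         p_hi: float = P_HI_DEFAULT, min_spikes: int = 100,
                         window_ms=EDGE_WINDOW_MS) -> list[Edge]:
    """Scan all ordered unit pairs of a ``SpikeDataset`` for edges."""
    edges: list[Edge] = []
    uids = spikes.unit_ids
    trains = {u: spikes.spike_times[u] for u in uids}
    if intervals is not None:
        trains = {u: t[in_intervals(t, intervals)] for u, t in trains.items()}
    for u in uids:
        if trains[u].size < min_spikes:
            continue
        for v in uids:
            if v == u or trains[v].size < min_spikes:
                continue
            ccg = compute_ccg(trains[u], trains[v], bin_ms, halfwidth_ms)
            pred = baseline_predictor(ccg, sigma_ms)
            found = detect_edges(ccg, pred, pre=u, post=v, window_ms=window_ms,
                                 p_hi=p_hi)
            for e in found:
                p, p2b = transmission_probability(ccg, window_ms=window_ms)
                e.transmission["ALL"] = p
                e.peak_to_baseline["ALL"] = p2b
            edges.extend(found)
    return edges
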