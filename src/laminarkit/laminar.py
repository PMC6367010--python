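"""Laminar mapping: spike-power landmark, current source density (CSD)
landmarks, normalized-depth warping, gamma-coherence clustering of
recording sites, and ICA decomposition of gamma-band LFPs.

Five physiological landmarks anchor depth across sessions: a superficial
CSD source (a), the layer 3/4 border sink (b), the 500 Hz - 5 kHz
spike-power maximum in mid layer 5 (c), a deep sink at the layer 5/6
border (d) and a deep source in lower layer 6 (e).  Sign convention for
CSD: sinks (net inward current) are negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.metrics import adjusted_rand_score

from ._utils import bandpass

__all__ = [
    "LandmarkError",
    "LaminarMap",
    "CsdMap",
    "CoherenceClustering",
    "mua_power_profile",
    "event_triggered_csd",
    "find_landmarks",
    "normalize_depth",
    "DepthWarp",
    "partition_energy",
    "gradient_descent_cluster",
    "gamma_ica",
    "GammaIca",
]

LANDMARK_ORDER = ("a", "b", "c", "d", "e")


class LandmarkError(RuntimeError):
    """Landmark ordering or detectability failure; carries diagnostics."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass
class CsdMap:
    csd: np.ndarray            # (n_channels, n_times); first/last rows NaN
    times_s: np.ndarray
    depths_um: np.ndarray
    n_events: int
    trigger: str = ""


@dataclass
class CoherenceClustering:
    C: np.ndarray
    assignment: np.ndarray       # channel -> cluster id (0..K-1, depth-ordered)
    energy: float
    n_clusters: int
    n_restarts: int
    consistency: float           # mean adjusted agreement vs modal solution
    restart_energies: np.ndarray


@dataclass
class GammaIca:
    loadings: np.ndarray         # (n_components, n_channels), depth order
    time_series: np.ndarray      # (n_components, n_samples)
    relative_power: np.ndarray   # variance share per component (sums <= 1)
    is_uniform: np.ndarray       # volume-conducted flag per component
    laminar_ics: np.ndarray      # indices of the retained laminar components


@dataclass
class LaminarMap:
    landmark_depths_um: dict
    warp: "DepthWarp | None" = None
    cluster_of_channel: np.ndarray | None = None
    ic_loadings: np.ndarray | None = None
    ic_relative_power: np.ndarray | None = None


# --------------------------------------------------------------------------
# spike-band power profile


def mua_power_profile(rec_wideband, band=(500.0, 5000.0)) -> np.ndarray:
    """Per-channel power in the multi-unit (spike) band.

    Requires wideband data (fs >= 10 kHz).  The profile maximum marks
    landmark c (mid layer 5, aggregate firing of large pyramidal cells).
    """
    if rec_wideband.fs < 10000:
        raise ValueError(f"fs {rec_wideband.fs} too low for the {band} Hz band")
    x = rec_wideband.voltage_uv()
    y = bandpass(x, rec_wideband.fs, band[0], min(band[1], 0.95 * rec_wideband.fs / 2))
    return np.mean(y ** 2, axis=1)


def profile_peak_depth(profile: np.ndarray, depths_um: np.ndarray) -> float:
    if np.ptp(profile) < 1e-12 or not np.all(np.isfinite(profile)):
        raise LandmarkError("flat or invalid power profile; no peak",
                            {"profile": profile})
    return float(depths_um[int(np.argmax(profile))])


# --------------------------------------------------------------------------
# current source density


def event_triggered_csd(rec_lfp, event_times, window_s=(-0.05, 0.2),
                        spatial_smooth: int = 0, trigger: str = "") -> CsdMap:
    """CSD of the event-triggered LFP average.

    ``CSD_i = -(V_{i-1} - 2 V_i + V_{i+1}) / dz^2`` on interior channels
    (outermost channels are NaN); conductivity is taken as 1 so units are
    relative.  Fewer than 10 events triggers a warning, not an error.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size < 10:
        warnings.warn(f"only {event_times.size} trigger events; CSD will be noisy")
    if event_times.size == 0:
        raise ValueError("no trigger events")
    fs = rec_lfp.fs
    i_lo = int(round(window_s[0] * fs))
    i_hi = int(round(window_s[1] * fs))
    n_t = i_hi - i_lo
    avg = np.zeros((rec_lfp.n_channels, n_t))
    n_used = 0
    for t0 in event_times:
        j = int(round(t0 * fs))
        if j + i_lo < 0 or j + i_hi > rec_lfp.n_samples:
            continue
        avg += rec_lfp.voltage_uv(t_start=(j + i_lo) / fs, t_stop=(j + i_hi) / fs)
        n_used += 1
    if n_used == 0:
        raise ValueError("no events with a complete window inside the recording")
    avg /= n_used
    if spatial_smooth > 0:
        from scipy.ndimage import uniform_filter1d

        avg = uniform_filter1d(avg, spatial_smooth, axis=0)
    dz = np.median(np.diff(rec_lfp.channel_depth_um))
    csd = np.full_like(avg, np.nan)
    csd[1:-1] = -(avg[:-2] - 2 * avg[1:-1] + avg[2:]) / dz**2
    times = (np.arange(i_lo, i_hi)) / fs
    return CsdMap(csd, times, rec_lfp.channel_depth_um.copy(), n_used, trigger)


# --------------------------------------------------------------------------
# landmarks


def find_landmarks(mua_profile: np.ndarray, downup_csd: CsdMap,
                   depths_um: np.ndarray | None = None,
                   post_window_s=(0.0, 0.15)) -> dict:
    """Locate landmarks a-e from the spike-power profile and the DOWN->UP
    transition CSD.

    c is the spike-power maximum; b and d are the most prominent sinks
    (negative CSD extremes within the post-transition window) above and
    below c; a is the most prominent source above b; e the most prominent
    source below d.  Prominence is peak absolute amplitude.  The ordering
    a < b < c < d < e is enforced; violation raises ``LandmarkError`` with
    a diagnostic profile map.
    """
    depths = downup_csd.depths_um if depths_um is None else np.asarray(depths_um)
    c_depth = profile_peak_depth(np.asarray(mua_profile), depths)

    tsel = (downup_csd.times_s >= post_window_s[0]) & \
           (downup_csd.times_s < post_window_s[1])
    if not tsel.any():
        raise LandmarkError("post-transition window empty", {})
    sub = downup_csd.csd[:, tsel]
    finite_rows = np.all(np.isfinite(sub), axis=1)
    if not finite_rows.any():
        raise LandmarkError("CSD has no finite interior channels", {})
    # spatial profile at the transition's dominant time (±10 ms): reading
    # each channel's extreme independently across the whole window would
    # mix the transition wave with neighbouring (opposite-polarity) delta
    # waves
    energy = np.nansum(sub[finite_rows] ** 2, axis=0)
    t_star = int(np.argmax(energy))
    dt = downup_csd.times_s[1] - downup_csd.times_s[0]
    half = max(int(round(0.010 / dt)), 1)
    lo = max(t_star - half, 0)
    profile = np.full(sub.shape[0], np.nan)
    profile[finite_rows] = np.mean(sub[finite_rows, lo:t_star + half + 1], axis=1)
    interior = np.isfinite(profile)

    diag = {"csd_extreme_profile": profile, "depths_um": depths, "c": c_depth}

    def deepest_extreme(mask, sign):
        cand = np.flatnonzero(mask & interior & (np.sign(profile) == sign))
        if cand.size == 0:
            raise LandmarkError("missing CSD landmark (flat or wrong-signed CSD)",
                                diag)
        return cand[np.argmax(np.abs(profile[cand]))]

    b_i = deepest_extreme(depths < c_depth, -1.0)
    d_i = deepest_extreme(depths > c_depth, -1.0)
    a_i = deepest_extreme(depths < depths[b_i], +1.0)
    e_i = deepest_extreme(depths > depths[d_i], +1.0)
    lm = {"a": float(depths[a_i]), "b": float(depths[b_i]), "c": c_depth,
          "d": float(depths[d_i]), "e": float(depths[e_i])}
    vals = [lm[k] for k in LANDMARK_ORDER]
    if not np.all(np.diff(vals) > 0):
        raise LandmarkError(f"landmark ordering violated: {lm}", diag)
    return lm


# --------------------------------------------------------------------------
# depth normalization


@dataclass
class DepthWarp:
    """Piecewise-linear monotone map from recorded to canonical depth.

    Exact at landmarks, linear extrapolation beyond a and e; the estimated
    pia lies 80 um above landmark a in canonical coordinates.
    """

    knots_in: np.ndarray
    knots_out: np.ndarray
    pia_offset_um: float = 80.0

    def __call__(self, depth_um):
        return _piecewise_linear(np.asarray(depth_um, dtype=float),
                                 self.knots_in, self.knots_out)

    def inverse(self, norm_depth_um):
        return _piecewise_linear(np.asarray(norm_depth_um, dtype=float),
                                 self.knots_out, self.knots_in)

    @property
    def pia_um(self) -> float:
        """Estimated pia surface in canonical coordinates."""
        return float(self.knots_out[0] - self.pia_offset_um)


def _piecewise_linear(x, xs, ys):
    out = np.interp(x, xs, ys)
    # linear extrapolation with the terminal segment slopes
    lo = x < xs[0]
    hi = x > xs[-1]
    if np.any(lo):
        s = (ys[1] - ys[0]) / (xs[1] - xs[0])
        out = np.where(lo, ys[0] + s * (x - xs[0]), out)
    if np.any(hi):
        s = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.where(hi, ys[-1] + s * (x - xs[-1]), out)
    return out if out.ndim else float(out)


def normalize_depth(landmark_depths: dict, canonical_depths: dict) -> DepthWarp:
    """Warp recorded depths so each landmark maps exactly to its canonical
    depth, stretching or compressing the stretches between landmarks."""
    xin = np.array([landmark_depths[k] for k in LANDMARK_ORDER], dtype=float)
    xout = np.array([canonical_depths[k] for k in LANDMARK_ORDER], dtype=float)
    if np.any(np.diff(xin) <= 0) or np.any(np.diff(xout) <= 0):
        raise ValueError("landmarks must be strictly ordered a<b<c<d<e")
    return DepthWarp(xin, xout)


# --------------------------------------------------------------------------
# gradient-descent coherence clustering


def partition_energy(C: np.ndarray, labels: np.ndarray) -> float:
    """Total interaction energy of a site partition.

    E = sum_A E_A with E_A = -(1/N_A) * sum_{i != j in A} C_ij (diagonal
    self-coherence excluded).  Lower is better: tightly coherent clusters
    have strongly negative energy.
    """
    labels = np.asarray(labels)
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            continue
        block = C[np.ix_(idx, idx)]
        total -= (block.sum() - np.trace(block)) / idx.size
    return float(total)


def gradient_descent_cluster(C: np.ndarray, n_restarts: int = 50,
                             seed=None, k0: int = 10,
                             max_sweeps: int = 500) -> CoherenceClustering:
    """Cluster recording sites by descending the coherence interaction
    energy with single-site moves.

    From a random initial assignment into ``k0`` groups, sites are visited
    in random order and moved to whichever cluster (including a fresh
    singleton) most lowers the total energy; when no single-site move
    helps, whole-cluster merges are attempted, and descent resumes until
    neither move kind lowers the energy.  The cluster count is emergent.
    The modal converged partition across restarts is returned, with a
    consistency score (mean adjusted Rand agreement of each restart with
    the modal solution).
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n) or not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("coherence matrix must be square and symmetric")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    Cz = C.copy()
    np.fill_diagonal(Cz, 0.0)

    results = []
    for _ in range(n_restarts):
        labels = rng.integers(0, min(k0, n), size=n)
        labels = _descend(Cz, labels, rng, max_sweeps)
        results.append(_canonical(labels))
    energies = np.array([partition_energy(C, lab) for lab in results])

    keys = [tuple(lab) for lab in results]
    uniq, counts = np.unique(keys, axis=0, return_counts=True)
    best = np.flatnonzero(counts == counts.max())
    # tie-break the modal partition by energy
    cand_energy = [partition_energy(C, u) for u in uniq[best]]
    modal = np.asarray(uniq[best[int(np.argmin(cand_energy))]], dtype=int)
    consistency = float(np.mean([adjusted_rand_score(modal, lab)
                                 for lab in results]))
    return CoherenceClustering(
        C=C, assignment=_canonical(modal),
        energy=partition_energy(C, modal),
        n_clusters=int(np.unique(modal).size),
        n_restarts=n_restarts, consistency=consistency,
        restart_energies=energies)


def _descend(Cz, labels, rng, max_sweeps):
    """Single-site moves accepted only when they strictly lower the total
    energy; visits in seeded random order; terminates at a local minimum.

    E_A = -S_A / N_A with S_A the off-diagonal coherence sum of cluster A;
    removing site i from A changes its term to -(S_A - 2 s_iA)/(N_A - 1)
    and adding it to B changes that term to -(S_B + 2 s_iB)/(N_B + 1),
    so each candidate move's exact energy change is O(K) to evaluate.
    """
    n = labels.size
    labels = labels.copy()

    def cluster_sums():
        ids = np.unique(labels)
        S = {lab: float(Cz[np.ix_(labels == lab, labels == lab)].sum())
             for lab in ids}
        N = {lab: int((labels == lab).sum()) for lab in ids}
        return ids, S, N

    def term(s, m):
        return -s / m if m >= 2 else 0.0

    for _ in range(max_sweeps):
        # single-site moves to convergence
        moved_any = True
        sweeps = 0
        while moved_any and sweeps < max_sweeps:
            moved_any = False
            sweeps += 1
            ids, S, N = cluster_sums()
            for i in rng.permutation(n):
                cur = labels[i]
                s_i = {lab: float(Cz[i, labels == lab].sum()) for lab in ids}
                eA_before = term(S[cur], N[cur])
                eA_after = term(S[cur] - 2 * s_i[cur], N[cur] - 1)
                best_delta, best_target = -1e-12, None
                for lab in ids:
                    if lab == cur:
                        continue
                    delta = (eA_after + term(S[lab] + 2 * s_i[lab], N[lab] + 1)
                             - eA_before - term(S[lab], N[lab]))
                    if delta < best_delta:
                        best_delta, best_target = delta, lab
                # splitting off into a fresh singleton (its own term is 0)
                delta_new = eA_after - eA_before
                if delta_new < best_delta:
                    best_delta, best_target = delta_new, "__new__"
                if best_target is not None:
                    S[cur] -= 2 * s_i[cur]
                    N[cur] -= 1
                    if best_target == "__new__":
                        new_lab = int(labels.max()) + 1
                        labels[i] = new_lab
                        S[new_lab], N[new_lab] = 0.0, 1
                    else:
                        S[best_target] += 2 * s_i[best_target]
                        N[best_target] += 1
                        labels[i] = best_target
                    if N[cur] == 0:
                        del S[cur], N[cur]
                    ids = np.array(sorted(N))
                    moved_any = True
        # whole-cluster merges (escape the fragmentation local minima that
        # single-site moves cannot leave)
        ids, S, N = cluster_sums()
        best_delta, best_pair = -1e-12, None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                cross = float(Cz[np.ix_(labels == a, labels == b)].sum())
                delta = (term(S[a] + S[b] + 2 * cross, N[a] + N[b])
                         - term(S[a], N[a]) - term(S[b], N[b]))
                if delta < best_delta:
                    best_delta, best_pair = delta, (a, b)
        if best_pair is None:
            break
        labels[labels == best_pair[1]] = best_pair[0]
    return labels


def _canonical(labels) -> np.ndarray:
    """Relabel clusters by order of first appearance (canonical form)."""
    labels = np.asarray(labels)
    mapping = {}
    out = np.empty_like(labels)
    nxt = 0
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


# --------------------------------------------------------------------------
# gamma-band ICA


def gamma_ica(rec_lfp, band=(30.0, 100.0), n_pcs: int = 10, n_ics: int = 6,
              seed=None, uniform_cv: float = 0.1, max_retries: int = 5,
              intervals=None) -> GammaIca:
    """ICA decomposition of band-passed LFPs into depth-localized sources.

    The band-passed channel signals are reduced to ``n_pcs`` principal
    components, unmixed with FastICA, and each component's channel loading
    (back-projection through the PCA) is returned in depth order with the
    maximum-absolute element positive.  Components are ranked by the
    variance they explain; shares are normalized within the PCA
    reconstruction and scaled by the PCA-captured fraction, so they sum to
    at most 1.  Components with near-flat loadings (coefficient of
    variation < ``uniform_cv``) are flagged as volume-conducted and
    excluded from the ``n_ics`` laminar components.
    """
    if rec_lfp.n_channels < n_pcs:
        raise ValueError("need at least n_pcs channels")
    # band-pass channel chunks and keep float32: the full-session matrix
    # is large and ICA does not need double precision
    mask = None
    if intervals is not None:
        from ._utils import sample_mask

        mask = sample_mask(rec_lfp.n_samples, rec_lfp.fs, intervals)
    cols = []
    for i in range(0, rec_lfp.n_channels, 8):
        xi = rec_lfp.voltage_uv(channels=slice(i, min(i + 8, rec_lfp.n_channels)))
        if mask is not None:
            xi = xi[:, mask]
        xb = bandpass(xi, rec_lfp.fs, band[0], min(band[1], 0.95 * rec_lfp.fs / 2))
        cols.append(xb.T.astype(np.float32))
    X = np.concatenate(cols, axis=1)          # (time, ch)
    del cols
    X = X - X.mean(0)

    pca = PCA(n_components=n_pcs, svd_solver="full")
    # ICA iterations run on the small score matrix in double precision
    Y = pca.fit_transform(X).astype(np.float64)
    pca_frac = float(np.sum(pca.explained_variance_ratio_))

    rng = np.random.default_rng(seed)
    S = mixing = None
    for _ in range(max_retries):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=UserWarning)
                ica = FastICA(n_components=n_pcs, whiten="unit-variance",
                              max_iter=1000, tol=1e-3,
                              random_state=int(rng.integers(2**31)))
                S = ica.fit_transform(Y)
                mixing = ica.mixing_          # Y ~= S @ mixing.T
            break
        except UserWarning:
            S = mixing = None
            continue
    if S is None:
        raise RuntimeError("FastICA failed to converge after retries")

    load = pca.components_.T @ mixing         # (ch, n_pcs)
    # variance explained by each component's back-projection:
    # ||s a^T||_F^2 = ||s||^2 ||a||^2
    comp_var = np.array([np.sum(S[:, k] ** 2) * np.sum(load[:, k] ** 2)
                         for k in range(n_pcs)])
    shares = comp_var / max(comp_var.sum(), 1e-300) * pca_frac
    order = np.argsort(shares)[::-1]
    load = load[:, order].T                   # (n_pcs, ch)
    S = S[:, order].T
    shares = shares[order]

    # sign convention: maximum-absolute loading element positive
    for k in range(load.shape[0]):
        j = int(np.argmax(np.abs(load[k])))
        if load[k, j] < 0:
            load[k] = -load[k]
            S[k] = -S[k]

    cv = np.array([np.std(l) / max(np.abs(np.mean(l)), 1e-12) for l in load])
    is_uniform = cv < uniform_cv
    laminar = np.array([k for k in range(load.shape[0]) if not is_uniform[k]],
                       dtype=int)[:n_ics]
    return GammaIca(load, S, shares, is_uniform, laminar)
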