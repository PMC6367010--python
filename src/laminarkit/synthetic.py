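"""Ground-truth-annotated synthetic laminar sessions.

Emulates the statistical structure a single-shank 64-site V1 recording is
assumed to have by the downstream analyses:

* six band-limited (30-100 Hz) gamma sources with Gaussian depth loadings
  centered in distinct layers, plus one spatially uniform volume-conducted
  broadband gamma term (default 0.34 of gamma-band LFP variance);
* non-REM slow oscillation with alternating DOWN/UP epochs (gamma-
  distributed DOWN durations with 50-150 ms mode, lognormal UP durations),
  a delta-band LFP deflection per DOWN and a DOWN->UP transition wave whose
  current source density carries the landmark dipoles (superficial source
  a, layer 3/4 sink b, deep sink d, deep source e);
* a 3-6 Hz waking rhythm strongest in layer 4, occurring in bouts of
  immobility; REM theta; a high-frequency common "EMG" term during waking;
  a 100-400 Hz spiking hash whose envelope collapses during DOWN states;
* lognormal unit firing rates, bimodal trough-to-peak waveform latencies,
  von Mises phase coupling of spikes to layer gamma and the waking rhythm,
  DOWN-silenced units plus rare DOWN-state-active units, and planted
  monosynaptic couplings realized by spike injection (excitatory) or
  thinning (inhibitory) in a 1.5-4 ms lag window, so the expected excess
  spike count per presynaptic spike equals the configured transmission
  probability exactly.

Everything is a deterministic function of ``SimConfig`` (including the
seed): identical configs produce bit-identical sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.signal import hilbert
from scipy.special import i0, i1

from ._utils import bandpass, lowpass, sample_mask
from .io import ConfigurationError, ProbeRecording, SpikeDataset, make_event_table

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_session",
    "simulate_laminar_gamma",
    "simulate_wideband_snippet",
    "simulate_spike_network",
    "poisson_train",
    "inhomogeneous_poisson",
    "phase_coupled_intensity",
    "make_waveform",
    "default_state_plan",
]


# --------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Study conditions for a synthetic session.  Defaults mirror the
    recording setup the analyses target (64 sites at 20 um pitch, 20 kHz
    wideband, 1.25 kHz LFP)."""

    n_channels: int = 64
    pitch_um: float = 20.0
    fs_wideband: float = 20000.0
    fs_lfp: float = 1250.0
    duration_s: float = 600.0
    seed: int = 0
    uv_per_bit: float = 0.195

    # brain-state plan: ((label, duration_s), ...); None -> all WAKE
    state_plan: tuple | None = None

    # gamma sources
    n_gamma_sources: int = 6
    gamma_band: tuple = (30.0, 100.0)
    gamma_source_amp_uv: float = 30.0
    gamma_source_sigma_um: float = 60.0
    gamma_source_centers_um: tuple | None = None   # None -> layer centers
    volume_conducted_share: float = 0.34

    # additive noise: white (electrode/thermal) plus 1/f background, the
    # dominant broadband component of any cortical LFP
    noise_uv: float = 5.0
    pink_noise_uv: float = 15.0

    # slow oscillation (NREM)
    down_rate_hz: float = 0.55          # DOWN events per second of NREM
    down_dur_shape: float = 6.0         # gamma-distributed durations,
    down_dur_mean_s: float = 0.11       # mode ~90 ms (50-150 ms range)
    down_dur_fixed_s: float | None = None
    up_dur_mu: float = float(np.log(0.9))   # lognormal UP durations
    up_dur_sigma: float = 0.55
    delta_amp_uv: float = 300.0
    delta_pad_s: float = 0.02           # delta wave slightly outlasts DOWN
    # the transition wave is normalized on its (broad) voltage profile;
    # 600 uV peak corresponds to a modest ~0.024 uV/um^2 landmark CSD
    transition_amp_uv: float = 600.0
    transition_dur_s: float = 0.12

    # 3-6 Hz waking rhythm (layer 4)
    rhythm_freq_hz: float = 4.0
    rhythm_amp_uv: float = 120.0
    rhythm_sigma_um: float = 150.0

    # REM theta (volume-conducted, spatially uniform)
    theta_freq_hz: float = 7.0
    theta_amp_uv: float = 100.0

    # high-frequency terms
    emg_wake_uv: float = 10.0           # common 300-600 Hz noise in WAKE
    emg_sleep_factor: float = 0.05
    hash_uv: float = 8.0                # 100-400 Hz spiking hash
    hash_down_factor: float = 0.08

    # units
    n_units: int = 40
    rate_lognormal_mu: float = float(np.log(3.0))
    rate_lognormal_sigma: float = 0.8
    rate_clip_hz: tuple = (0.5, 25.0)
    frac_inhibitory: float = 0.25
    deep_wake_nrem_ratio: float = 2.0
    gamma_coupling_strength: float = 0.35     # target mean resultant length
    gamma_preferred_phase: float = float(np.pi)
    rhythm_coupling_strength: float = 0.25
    rhythm_preferred_phase: float = float(np.pi)
    down_silence_factor: float = 0.02
    # DOWN-state-active units are ~0.3% of cortical populations; a
    # realistic few-dozen-unit session contains none unless asked for
    n_down_active: int = 0
    down_active_rate_down_hz: float = 35.0
    down_active_rate_up_hz: float = 4.3

    # connectivity: ((pre, post, p), ...); p > 0 excitatory injection
    # probability, p < 0 inhibitory thinning fraction
    edges: tuple = ()
    edge_lag_ms: tuple = (1.5, 4.0)

    # optotagging
    n_opto_pulses: int = 200
    n_opto_tagged: int = 2
    opto_p_respond: float = 0.8
    opto_latency_ms: float = 2.5
    opto_latency_jitter_ms: float = 0.5

    def validate(self) -> None:
        ratio = self.fs_wideband / self.fs_lfp
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(
                f"fs_wideband {self.fs_wideband} must be an integer multiple "
                f"of fs_lfp {self.fs_lfp}"
            )
        if self.duration_s < 60:
            raise ConfigurationError("duration_s must be >= 60 s")
        for name in ("fs_wideband", "fs_lfp", "down_rate_hz", "rhythm_freq_hz",
                     "theta_freq_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    # geometry helpers -----------------------------------------------------

    @property
    def depths_um(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.pitch_um

    @property
    def span_um(self) -> float:
        return (self.n_channels - 1) * self.pitch_um

    def layer_boundaries_um(self) -> np.ndarray:
        """Depths of the L1/2, L2/3, L3/4, L4/5, L5/6 boundaries.

        Fractions of the probe span follow mouse V1 layer thicknesses
        (L1 ~90, L2 ~120, L3 ~160, L4 ~140, L5 ~280, L6 ~470 um on a
        ~1260 um column).
        """
        frac = np.array([0.072, 0.167, 0.294, 0.405, 0.627])
        return frac * self.span_um

    def layer_of_depth(self, depth_um) -> np.ndarray:
        b = self.layer_boundaries_um()
        return np.digitize(np.atleast_1d(depth_um), b) + 1

    def landmark_depths_um(self) -> dict:
        """Planted physiological landmarks (um): a superficial source,
        b layer 3/4 border sink, c mid-layer-5 spike-power peak,
        d deep (L5/6) sink, e deep source."""
        s = self.span_um
        return {
            "a": 0.10 * s,
            "b": 0.294 * s,
            "c": 0.516 * s,
            "d": 0.627 * s,
            "e": 0.865 * s,
        }


def default_state_plan(duration_s: float) -> tuple:
    """WAKE/NREM/REM cycle filling the session (WAKE bouts >= 7 min)."""
    cycle = [("WAKE", 480.0), ("NREM", 360.0), ("REM", 150.0)]
    plan: list[tuple[str, float]] = []
    t, i = 0.0, 0
    while t < duration_s:
        label, dur = cycle[i % len(cycle)]
        dur = min(dur, duration_s - t)
        plan.append((label, dur))
        t += dur
        i += 1
    return tuple(plan)


# --------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Everything the analyses are expected to recover."""

    layer_of_channel: np.ndarray            # (n_channels,), values 1..6
    source_loadings: np.ndarray             # (n_sources[+1 uniform], n_channels)
    landmark_depths_um: dict
    state_intervals: list                   # (start, end, label)
    downup_intervals: list                  # (start, end, "DOWN"|"UP")
    unit_table: pd.DataFrame
    true_edges: list                        # (pre, post, sign, p, lag window)
    config: SimConfig | None = None

    def intervals(self, label: str) -> list:
        return [(s, e) for s, e, lab in self.state_intervals if lab == label]

    def down_intervals(self) -> list:
        return [(s, e) for s, e, lab in self.downup_intervals if lab == "DOWN"]

    def up_intervals(self) -> list:
        return [(s, e) for s, e, lab in self.downup_intervals if lab == "UP"]

    def frame_labels(self, n_frames: int, step_s: float = 1.0) -> np.ndarray:
        """Per-frame state labels at frame centers."""
        centers = (np.arange(n_frames) + 0.5) * step_s
        out = np.array(["WAKE"] * n_frames, dtype=object)
        for s, e, lab in self.state_intervals:
            out[(centers >= s) & (centers < e)] = lab
        return out

    def to_dict(self) -> dict:
        return {
            "layer_of_channel": self.layer_of_channel.tolist(),
            "source_loadings": self.source_loadings.tolist(),
            "landmark_depths_um": self.landmark_depths_um,
            "state_intervals": [list(x) for x in self.state_intervals],
            "downup_intervals": [list(x) for x in self.downup_intervals],
            "unit_table": self.unit_table.to_dict(orient="list"),
            "true_edges": [list(x) for x in self.true_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            layer_of_channel=np.asarray(d["layer_of_channel"], dtype=int),
            source_loadings=np.asarray(d["source_loadings"], dtype=float),
            landmark_depths_um=dict(d["landmark_depths_um"]),
            state_intervals=[tuple(x) for x in d["state_intervals"]],
            downup_intervals=[tuple(x) for x in d["downup_intervals"]],
            unit_table=pd.DataFrame(d["unit_table"]),
            true_edges=[tuple(x) for x in d["true_edges"]],
        )


# --------------------------------------------------------------------------
# elemental generators


def poisson_train(rate_hz: float, duration_s: float, rng: np.random.Generator,
                  t0: float = 0.0) -> np.ndarray:
    """Homogeneous Poisson spike train on [t0, t0 + duration)."""
    n = rng.poisson(rate_hz * duration_s)
    return t0 + np.sort(rng.random(n) * duration_s)


def inhomogeneous_poisson(rate_t: np.ndarray, fs: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Spikes from a per-sample intensity (Hz); at most one per sample,
    uniformly jittered within the sample."""
    lam = np.asarray(rate_t, dtype=float) / fs
    hits = np.flatnonzero(rng.random(lam.size) < lam)
    return (hits + rng.random(hits.size)) / fs


def _kappa_from_R(R: float) -> float:
    """Invert the von Mises mean-resultant-length relation R = I1(k)/I0(k)."""
    if R <= 0:
        return 0.0
    lo, hi = 1e-6, 50.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if i1(mid) / i0(mid) < R:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def phase_coupled_intensity(phase_t: np.ndarray, R_target: float,
                            preferred_phase: float) -> np.ndarray:
    """Unit-mean von Mises modulation factor for a phase time series.

    Spikes thinned by this factor have a von Mises phase distribution with
    mean resultant length ~= ``R_target`` and circular mean at
    ``preferred_phase`` (exact when the phase visits angles uniformly)."""
    kappa = _kappa_from_R(R_target)
    if kappa == 0:
        return np.ones_like(phase_t)
    return np.exp(kappa * np.cos(phase_t - preferred_phase)) / i0(kappa)


def make_waveform(tp_ms: float, fs: float = 20000.0, n_samples: int = 64,
                  positive: bool = False, amp_uv: float = 100.0) -> np.ndarray:
    """Parametric extracellular mean waveform (difference of Gaussians).

    A negative trough at 1.0 ms followed by a positive peak ``tp_ms`` later
    (the trough-to-peak latency); ``positive=True`` inverts the template.
    """
    t = np.arange(n_samples) / fs * 1e3  # ms
    t_trough = 1.0
    wf = -np.exp(-0.5 * ((t - t_trough) / 0.10) ** 2)
    wf += 0.45 * np.exp(-0.5 * ((t - t_trough - tp_ms) / (0.18 + 0.18 * tp_ms)) ** 2)
    wf *= amp_uv
    return -wf if positive else wf


def _apply_edges(trains: dict[int, np.ndarray], edges, lag_ms,
                 rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Realize planted monosynaptic couplings by injection / thinning."""
    lag_lo, lag_hi = lag_ms[0] * 1e-3, lag_ms[1] * 1e-3
    out = {u: t.copy() for u, t in trains.items()}
    for pre, post, p in edges:
        pre_t = trains[int(pre)]
        if p > 0:
            hit = rng.random(pre_t.size) < p
            inject = pre_t[hit] + rng.uniform(lag_lo, lag_hi, int(hit.sum()))
            out[int(post)] = np.sort(np.concatenate([out[int(post)], inject]))
        elif p < 0:
            post_t = out[int(post)]
            lo = np.searchsorted(pre_t, post_t - lag_hi, side="left")
            hi = np.searchsorted(pre_t, post_t - lag_lo, side="right")
            exposed = hi > lo
            kill = exposed & (rng.random(post_t.size) < -p)
            out[int(post)] = post_t[~kill]
    return out


# --------------------------------------------------------------------------
# laminar gamma


def _bursty_band_noise(n: int, fs: float, band, rng: np.random.Generator,
                       env_cutoff_hz: float = 2.0, env_strength: float = 0.6
                       ) -> np.ndarray:
    """Band-limited noise with a slow lognormal burst envelope (unit
    variance output).

    The multiplicative envelope makes the source heavy-tailed
    (super-Gaussian), as cortical gamma bursts are; blind source
    separation of the mixture relies on this non-Gaussianity.  The
    envelope exponent is clipped to +-2.5 SD so burst power spans roughly
    an order of magnitude and no single excursion dominates the session
    variance.
    """
    x = bandpass(rng.standard_normal(n), fs, band[0], band[1])
    env = lowpass(rng.standard_normal(n), fs, env_cutoff_hz)
    env = np.exp(env_strength * np.clip(env / max(np.std(env), 1e-12), -2.5, 2.5))
    s = x * env
    return s / max(np.std(s), 1e-12)


def simulate_laminar_gamma(cfg: SimConfig, rng: np.random.Generator | None = None,
                           return_sources: bool = False):
    """Generate the multichannel gamma-band signal and its depth loadings.

    Returns ``(signal_uv, loadings)`` where ``signal_uv`` is channels x
    time (LFP rate) and ``loadings`` stacks the laminar source loadings
    (unit maximum each) plus, when ``volume_conducted_share > 0``, a final
    spatially uniform row.  With ``return_sources=True`` the per-source
    time series (including the uniform one) are returned as a third value.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.n_gamma_sources < 2:
        raise ConfigurationError("need >= 2 gamma sources")
    depths = cfg.depths_um
    n = int(round(cfg.duration_s * cfg.fs_lfp))
    if cfg.gamma_source_centers_um is not None:
        centers = np.asarray(cfg.gamma_source_centers_um, dtype=float)
        sigmas = np.full(centers.size, cfg.gamma_source_sigma_um)
    else:
        b = np.concatenate([[0.0], cfg.layer_boundaries_um(), [cfg.span_um]])
        mids = (b[:-1] + b[1:]) / 2
        pick = np.linspace(0, 5, cfg.n_gamma_sources).round().astype(int)
        centers = mids[pick]
        sigmas = 0.45 * np.diff(b)[pick]
    if len(np.unique(np.round(centers, 6))) < len(centers):
        warnings.warn("gamma source centers are not all distinct")

    # flat-top (generalized Gaussian, p=6) depth loadings: a layer's gamma
    # is generated throughout the layer and falls off sharply at its
    # boundaries, matching the observed across-boundary coherence drop
    loadings = np.exp(-0.5 * ((depths[None, :] - centers[:, None])
                              / sigmas[:, None]) ** 6)
    loadings /= loadings.max(axis=1, keepdims=True)

    # every source spans the whole gamma band; sources are distinguished
    # by independent bursty envelopes, not by disjoint sub-bands
    sources = np.empty((cfg.n_gamma_sources, n))
    for k in range(cfg.n_gamma_sources):
        sources[k] = _bursty_band_noise(n, cfg.fs_lfp, cfg.gamma_band, rng)
    amp = cfg.gamma_source_amp_uv
    sig = amp * (loadings.T @ sources)          # (ch, n)

    if cfg.volume_conducted_share > 0:
        v = cfg.volume_conducted_share
        lam_var = float(np.mean(np.var(sig, axis=1)))
        vc = _bursty_band_noise(n, cfg.fs_lfp, cfg.gamma_band, rng)
        vc_amp = np.sqrt(v / (1 - v) * lam_var)
        sig = sig + vc_amp * vc[None, :]
        loadings = np.vstack([loadings, np.ones(cfg.n_channels)])
        sources = np.vstack([sources, vc])
    if return_sources:
        return sig, loadings, sources
    return sig, loadings


# --------------------------------------------------------------------------
# slow-oscillation scaffolding


def _draw_downup(cfg: SimConfig, nrem_intervals, rng: np.random.Generator):
    """Alternating UP/DOWN intervals inside each NREM bout."""
    out = []
    for s, e in nrem_intervals:
        t = s
        while t < e:
            up = float(rng.lognormal(cfg.up_dur_mu, cfg.up_dur_sigma))
            up = min(max(up, 0.15), e - t)
            out.append((t, t + up, "UP"))
            t += up
            if t >= e - 0.05:
                break
            if cfg.down_dur_fixed_s is not None:
                down = cfg.down_dur_fixed_s
            else:
                down = float(rng.gamma(cfg.down_dur_shape,
                                       cfg.down_dur_mean_s / cfg.down_dur_shape))
                down = min(max(down, 0.05), 0.4)
            down = min(down, e - t)
            out.append((t, t + down, "DOWN"))
            t += down
    return out


def _dipole_voltage_profile(cfg: SimConfig) -> np.ndarray:
    """Depth voltage profile whose CSD equals the landmark dipole pattern.

    Target CSD (sink negative): sources at landmarks a and e, sinks at b
    and d.  The discrete Poisson equation -(d2V/dz2) = CSD is solved with
    a grounded top (toward the pia) and a zero-gradient bottom, so the
    second-difference CSD estimator recovers the planted pattern exactly
    on interior channels while the deep channels keep the large slow-wave
    amplitude characteristic of deep layers.
    """
    depths = cfg.depths_um
    lm = cfg.landmark_depths_um()
    sigma = 2.0 * cfg.pitch_um
    csd = np.zeros(cfg.n_channels)
    for key, sign in (("a", +1.0), ("b", -1.0), ("d", -1.0), ("e", +1.0)):
        csd += sign * np.exp(-0.5 * ((depths - lm[key]) / sigma) ** 2)
    dz = cfg.pitch_um
    n = cfg.n_channels
    A = np.zeros((n, n))
    idx = np.arange(1, n - 1)
    A[idx, idx - 1] = -1.0 / dz**2
    A[idx, idx] = 2.0 / dz**2
    A[idx, idx + 1] = -1.0 / dz**2
    A[0, 0] = 1.0                      # grounded at the top
    A[-1, -1], A[-1, -2] = 1.0, -1.0   # zero gradient at the bottom
    rhs = csd.copy()
    rhs[0] = rhs[-1] = 0.0
    v = np.linalg.solve(A, rhs)
    return v / np.max(np.abs(v))


def _pink_noise(shape, fs: float, rng: np.random.Generator,
                rms_uv: float, f_min: float = 0.5) -> np.ndarray:
    """1/f-power background noise with the given RMS, independent per row."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = 1.0 / np.sqrt(np.maximum(freqs, f_min))
    gain[0] = 0.0
    white = rng.standard_normal(shape)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n, axis=-1)
    shaped *= rms_uv / np.maximum(shaped.std(axis=-1, keepdims=True), 1e-12)
    return shaped


def _hann_bump(n_lfp: int, fs: float, start: float, end: float) -> tuple:
    i0_ = max(int(start * fs), 0)
    i1_ = min(int(end * fs), n_lfp)
    if i1_ <= i0_:
        return i0_, np.zeros(0)
    return i0_, np.hanning(i1_ - i0_)


# --------------------------------------------------------------------------
# session assembly


def simulate_session(cfg: SimConfig):
    """Generate a full session.

    Returns ``(rec_lfp, spikes, events, truth)``: the LFP-rate
    ``ProbeRecording``, a ``SpikeDataset`` with per-unit mean waveforms,
    an event table (light pulses), and the ``GroundTruth``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_lfp
    n = int(round(cfg.duration_s * fs))
    t_ax = np.arange(n) / fs
    depths = cfg.depths_um

    # ---- states
    plan = cfg.state_plan if cfg.state_plan is not None else (("WAKE", cfg.duration_s),)
    state_intervals = []
    t = 0.0
    for label, dur in plan:
        dur = min(dur, cfg.duration_s - t)
        if dur <= 0:
            break
        state_intervals.append((t, t + dur, label))
        t += dur
    nrem = [(s, e) for s, e, lab in state_intervals if lab == "NREM"]
    wake = [(s, e) for s, e, lab in state_intervals if lab == "WAKE"]
    rem = [(s, e) for s, e, lab in state_intervals if lab == "REM"]
    downup = _draw_downup(cfg, nrem, rng)
    down_iv = [(s, e) for s, e, lab in downup if lab == "DOWN"]

    wake_mask = sample_mask(n, fs, wake) if wake else np.zeros(n, bool)
    rem_mask = sample_mask(n, fs, rem) if rem else np.zeros(n, bool)
    down_mask = sample_mask(n, fs, down_iv) if down_iv else np.zeros(n, bool)

    # ---- LFP: laminar gamma + volume conduction
    lfp, loadings, sources = simulate_laminar_gamma(cfg, rng, return_sources=True)
    lfp = lfp.astype(np.float32)

    # ---- slow oscillation waves
    v_profile = _dipole_voltage_profile(cfg)
    lm = cfg.landmark_depths_um()
    ch_c = int(np.argmin(np.abs(depths - lm["c"])))
    v_down = v_profile * np.sign(v_profile[ch_c] if v_profile[ch_c] != 0 else 1.0)
    for s, e in down_iv:
        # delta wave slightly outlasts the DOWN state, in proportion to it
        pad = min(cfg.delta_pad_s, 0.25 * (e - s))
        i0_, bump = _hann_bump(n, fs, s - pad, e + pad)
        if bump.size:
            lfp[:, i0_:i0_ + bump.size] += (
                cfg.delta_amp_uv * np.outer(v_down, bump).astype(np.float32))
        # DOWN->UP transition wave carrying the landmark CSD dipoles; the
        # Hann envelope has zero edge slope, so the wave stays band-limited
        i1_, tw = _hann_bump(n, fs, e, e + cfg.transition_dur_s)
        if tw.size:
            lfp[:, i1_:i1_ + tw.size] += (
                cfg.transition_amp_uv * np.outer(v_profile, tw).astype(np.float32))

    # ---- 3-6 Hz waking rhythm (bouts of immobility, layer 4 maximum)
    rhythm_phase = 2 * np.pi * cfg.rhythm_freq_hz * t_ax
    bouts = lowpass(rng.standard_normal(n), fs, 0.15)
    bout_env = lowpass((bouts > 0).astype(float), fs, 2.0).clip(0, 1)
    rhythm_env = bout_env * wake_mask
    rhythm_load = np.exp(-0.5 * ((depths - lm["b"]) / cfg.rhythm_sigma_um) ** 2)
    rhythm_t = np.cos(rhythm_phase) * rhythm_env
    lfp += cfg.rhythm_amp_uv * np.outer(rhythm_load, rhythm_t).astype(np.float32)

    # ---- REM theta (volume-conducted from hippocampus: uniform loading)
    if rem_mask.any():
        theta = np.cos(2 * np.pi * cfg.theta_freq_hz * t_ax) * rem_mask
        theta = cfg.theta_amp_uv * theta
        lfp += theta[None, :].astype(np.float32)

    # ---- EMG-like common high-frequency signal in WAKE
    emg = bandpass(rng.standard_normal(n), fs, 300.0, 600.0)
    emg /= max(np.std(emg), 1e-12)
    emg_env = np.where(wake_mask, 1.0, cfg.emg_sleep_factor)
    lfp += (cfg.emg_wake_uv * emg * emg_env)[None, :].astype(np.float32)

    # ---- spiking hash (100-400 Hz), DOWN-suppressed, strongest near c,
    # plus independent white and 1/f background noise.  Channels are
    # synthesized in chunks to bound peak memory.
    hash_env = np.where(down_mask, cfg.hash_down_factor, 1.0)[None, :]
    hash_load = 0.4 + np.exp(-0.5 * ((depths - lm["c"]) / 150.0) ** 2)
    for i in range(0, cfg.n_channels, 8):
        j = min(i + 8, cfg.n_channels)
        hs = bandpass(rng.standard_normal((j - i, n)), fs, 100.0, 400.0)
        hs /= np.maximum(hs.std(axis=1, keepdims=True), 1e-12)
        lfp[i:j] += (cfg.hash_uv * hash_load[i:j, None] * hs * hash_env
                     ).astype(np.float32)
        lfp[i:j] += (cfg.noise_uv
                     * rng.standard_normal((j - i, n))).astype(np.float32)
        if cfg.pink_noise_uv > 0:
            lfp[i:j] += _pink_noise((j - i, n), fs, rng,
                                    cfg.pink_noise_uv).astype(np.float32)

    rec = ProbeRecording(
        samples=np.clip(np.round(lfp / cfg.uv_per_bit), -32768, 32767).astype(np.int16),
        fs=fs,
        channel_depth_um=depths.astype(float),
        uv_per_bit=cfg.uv_per_bit,
        meta={"kind": "lfp", "seed": cfg.seed, "duration_s": cfg.duration_s},
    )
    del lfp

    # ---- units
    truth_units, trains, spikes = _simulate_units(
        cfg, rng, t_ax, sources, loadings, rhythm_phase, rhythm_env,
        wake_mask, rem_mask, down_mask, state_intervals, downup)

    # ---- optotagging pulses + injected responses
    events = _simulate_opto(cfg, rng, wake, truth_units, trains)
    for uid in trains:
        trains[uid] = trains[uid][(trains[uid] >= 0) & (trains[uid] < cfg.duration_s)]

    waveforms = {}
    peak_channel = {}
    for _, row in truth_units.iterrows():
        uid = int(row.unit_id)
        waveforms[uid] = make_waveform(
            row.tp_latency_ms, cfg.fs_wideband,
            positive=(row.true_class == "POSITIVE"))
        peak_channel[uid] = int(np.argmin(np.abs(depths - row.depth_um)))
    spikes = SpikeDataset(
        {u: np.sort(t) for u, t in trains.items()},
        waveforms=waveforms, waveform_fs=cfg.fs_wideband,
        peak_channel=peak_channel,
    )

    # landmarks live on the channel grid: snap to the nearest site depth
    lm_snapped = {k: float(depths[np.argmin(np.abs(depths - v))])
                  for k, v in lm.items()}
    truth = GroundTruth(
        layer_of_channel=np.asarray(
            [cfg.layer_of_depth(d)[0] for d in depths], dtype=int),
        source_loadings=loadings,
        landmark_depths_um=lm_snapped,
        state_intervals=state_intervals,
        downup_intervals=downup,
        unit_table=truth_units,
        true_edges=[(int(a), int(b), "E" if p > 0 else "I", float(p),
                     tuple(cfg.edge_lag_ms)) for a, b, p in cfg.edges],
        config=cfg,
    )
    # truth layer from dominant laminar source where one is planted
    lam = loadings[: cfg.n_gamma_sources]
    src_layer = cfg.layer_of_depth(
        np.array([cfg.depths_um[np.argmax(l)] for l in lam]))
    truth.layer_of_channel = src_layer[np.argmax(lam, axis=0)]
    return rec, spikes, events, truth


def _simulate_units(cfg, rng, t_ax, sources, loadings, rhythm_phase,
                    rhythm_env, wake_mask, rem_mask, down_mask,
                    state_intervals, downup):
    fs = cfg.fs_lfp
    n = t_ax.size
    n_units = cfg.n_units
    depths_span = cfg.span_um

    depth_u = rng.uniform(0.06 * depths_span, depths_span, n_units)
    layer_u = cfg.layer_of_depth(depth_u)
    is_I = rng.random(n_units) < cfg.frac_inhibitory
    cls = np.where(is_I, "I", "E").astype(object)
    # DOWN-active units sit in deep layer 6
    da_ids = rng.choice(n_units, size=min(cfg.n_down_active, n_units), replace=False)
    for uid in da_ids:
        cls[uid] = "DOWN_ACTIVE"
        depth_u[uid] = rng.uniform(0.85, 0.98) * depths_span
        layer_u[uid] = 6

    rates = np.clip(rng.lognormal(cfg.rate_lognormal_mu, cfg.rate_lognormal_sigma,
                                  n_units), *cfg.rate_clip_hz)
    rates[is_I] = np.clip(rates[is_I] * 2.0, *cfg.rate_clip_hz)  # interneurons faster
    tp = np.where(is_I, rng.normal(0.30, 0.04, n_units),
                  np.clip(rng.normal(0.85, 0.12, n_units), 0.62, None))
    tp = np.clip(tp, 0.15, None)

    wn_ratio = np.where(layer_u >= 5, cfg.deep_wake_nrem_ratio, 1.0)
    pref_phase = ((cfg.gamma_preferred_phase
                   + rng.normal(0, 0.1, n_units) + np.pi) % (2 * np.pi)) - np.pi

    # layer gamma phase: nearest planted source per unit
    lam = loadings[: cfg.n_gamma_sources]
    src_center = np.array([cfg.depths_um[np.argmax(l)] for l in lam])
    src_of_unit = np.argmin(np.abs(depth_u[:, None] - src_center[None, :]), axis=1)
    src_phase = {}
    for k in np.unique(src_of_unit):
        src_phase[k] = np.angle(hilbert(sources[k]))
    rhythm_mod_phase = np.mod(rhythm_phase + np.pi, 2 * np.pi) - np.pi

    nrem_mask = ~(wake_mask | rem_mask)
    trains: dict[int, np.ndarray] = {}
    exp_wake = np.empty(n_units)
    exp_nrem = np.empty(n_units)
    for uid in range(n_units):
        base = rates[uid]
        if cls[uid] == "DOWN_ACTIVE":
            lam_t = np.full(n, cfg.down_active_rate_up_hz)
            lam_t[down_mask] = cfg.down_active_rate_down_hz
        else:
            lam_t = np.full(n, base)
            lam_t[nrem_mask] = base / wn_ratio[uid]
            lam_t[down_mask] *= cfg.down_silence_factor
            lam_t *= phase_coupled_intensity(
                src_phase[src_of_unit[uid]], cfg.gamma_coupling_strength,
                pref_phase[uid])
            if rhythm_env.any() and cfg.rhythm_coupling_strength > 0:
                vm = phase_coupled_intensity(
                    rhythm_mod_phase, cfg.rhythm_coupling_strength,
                    cfg.rhythm_preferred_phase)
                lam_t *= 1.0 + rhythm_env * (vm - 1.0)
        trains[uid] = inhomogeneous_poisson(lam_t, fs, rng)
        exp_wake[uid] = float(lam_t[wake_mask].mean()) if wake_mask.any() else np.nan
        exp_nrem[uid] = float(lam_t[nrem_mask].mean()) if nrem_mask.any() else np.nan

    trains = _apply_edges(trains, cfg.edges, cfg.edge_lag_ms, rng)

    opto_pool = np.flatnonzero(is_I & (cls == "I"))
    tagged = set(rng.choice(opto_pool, size=min(cfg.n_opto_tagged, opto_pool.size),
                            replace=False).tolist()) if opto_pool.size else set()

    table = pd.DataFrame(
        {
            "unit_id": np.arange(n_units),
            "true_class": cls,
            "layer": layer_u,
            "depth_um": depth_u,
            "mean_rate_hz": rates,
            "tp_latency_ms": tp,
            "coupling_strength": np.where(cls == "DOWN_ACTIVE", 0.0,
                                          cfg.gamma_coupling_strength),
            "preferred_phase_rad": pref_phase,
            "wake_nrem_ratio": wn_ratio,
            "expected_rate_wake_hz": exp_wake,
            "expected_rate_nrem_hz": exp_nrem,
            "opto_tagged": [u in tagged for u in range(n_units)],
        }
    )
    return table, trains, None


def _simulate_opto(cfg, rng, wake_intervals, truth_units, trains):
    times, types, durs = [], [], []
    n_needed = cfg.n_opto_pulses
    for s, e in wake_intervals:
        if n_needed <= 0:
            break
        k = min(int(max(e - s - 20, 0)), n_needed)
        if k <= 0:
            continue
        pt = s + 10 + np.arange(k) * 1.0
        times.extend(pt.tolist())
        types.extend(["LIGHT_OPTO"] * k)
        durs.extend([0.010] * k)
        n_needed -= k
    pulse_times = np.array([t for t, ty in zip(times, types) if ty == "LIGHT_OPTO"])
    if pulse_times.size:
        tagged = truth_units.loc[truth_units.opto_tagged, "unit_id"]
        for uid in tagged:
            hit = rng.random(pulse_times.size) < cfg.opto_p_respond
            lat = rng.normal(cfg.opto_latency_ms, cfg.opto_latency_jitter_ms,
                             int(hit.sum())).clip(1.2, 5.8) * 1e-3
            inj = pulse_times[hit] + lat
            trains[int(uid)] = np.sort(np.concatenate([trains[int(uid)], inj]))
    return make_event_table(times, types, durs)


# --------------------------------------------------------------------------
# wideband snippet (for the MUA depth-power profile)


def simulate_wideband_snippet(cfg: SimConfig, duration_s: float = 20.0,
                              seed: int | None = None) -> ProbeRecording:
    """Short 20 kHz recording whose 500 Hz - 5 kHz power peaks at the
    planted mid-layer-5 landmark c (aggregate spiking of large layer 5
    cells).  Generated separately from the LFP session: the depth-power
    profile only needs seconds of data, not the whole session."""
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    n = int(duration_s * cfg.fs_wideband)
    depths = cfg.depths_um
    z_c = cfg.landmark_depths_um()["c"]
    profile = 1.0 + 2.0 * np.exp(-0.5 * ((depths - z_c) / 90.0) ** 2)
    x = rng.standard_normal((cfg.n_channels, n)).astype(np.float32)
    x *= (8.0 * profile)[:, None].astype(np.float32)
    return ProbeRecording(
        samples=np.clip(np.round(x / cfg.uv_per_bit), -32768, 32767).astype(np.int16),
        fs=cfg.fs_wideband,
        channel_depth_um=depths.astype(float),
        uv_per_bit=cfg.uv_per_bit,
        meta={"kind": "wideband", "duration_s": duration_s},
    )


# --------------------------------------------------------------------------
# light-weight spike network (connectivity benchmarks)


def simulate_spike_network(rates_hz, duration_s: float, edges=(),
                           seed: int | None = None, lag_ms=(1.5, 4.0),
                           state_intervals=None, state_rate_mult=None,
                           state_edge_scale=None):
    """Poisson spike network with planted monosynaptic couplings.

    ``edges`` is ``[(pre, post, p), ...]`` with ``p > 0`` the excitatory
    transmission probability (expected excess postsynaptic spikes per
    presynaptic spike in the lag window) and ``p < 0`` an inhibitory
    thinning fraction.  Optional per-state rate multipliers and per-state
    edge scaling (``{"WAKE": 2.0, ...}``) make transmission
    state-dependent.  Returns ``(SpikeDataset, true_edges)``.
    """
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates_hz, dtype=float)
    if np.any(rates <= 0):
        raise ConfigurationError("rates must be > 0")
    n_units = rates.size
    trains: dict[int, np.ndarray] = {}
    if state_intervals is None:
        for u in range(n_units):
            trains[u] = poisson_train(rates[u], duration_s, rng)
        trains = _apply_edges(trains, edges, lag_ms, rng)
    else:
        for u in range(n_units):
            parts = []
            for s, e, lab in state_intervals:
                mult = (state_rate_mult or {}).get(lab, 1.0)
                parts.append(poisson_train(rates[u] * mult, e - s, rng, t0=s))
            trains[u] = np.sort(np.concatenate(parts))
        # realize edges per state so transmission can differ across states
        out = {u: t.copy() for u, t in trains.items()}
        for s, e, lab in state_intervals:
            scale = (state_edge_scale or {}).get(lab, 1.0)
            seg_edges = [(a, b, p * scale) for a, b, p in edges]
            seg = {u: t[(t >= s) & (t < e)] for u, t in trains.items()}
            seg2 = _apply_edges(seg, seg_edges, lag_ms, rng)
            for u in out:
                extra = np.setdiff1d(seg2[u], seg[u])
                removed = np.setdiff1d(seg[u], seg2[u])
                keep = out[u][~np.isin(out[u], removed)]
                out[u] = np.sort(np.concatenate([keep, extra]))
        trains = out
    ds = SpikeDataset({u: np.sort(t[(t >= 0) & (t < duration_s)])
                       for u, t in trains.items()})
    true_edges = [(int(a), int(b), "E" if p > 0 else "I", float(p), tuple(lag_ms))
                  for a, b, p in edges]
    return ds, true_edges
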