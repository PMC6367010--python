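"""Shared signal-processing substrate: Morlet wavelet spectra, band
coherence, phase-amplitude coupling (modulation index), and spike-phase
coupling.

Phase convention used throughout the package: phase 0 at the oscillation
peak, +/-pi at the trough, increasing with time.  This is the convention
produced by taking the complex angle of an analytic (positive-frequency)
transform of a cosine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from ._utils import bandpass, envelope, sample_mask, welch_frames


# --------------------------------------------------------------------------
# Morlet continuous wavelet transform


@dataclass
class WaveletSpectrum:
    """Complex Morlet transform: ``coefficients[time, freq]`` at log-spaced
    ``freqs``; ``|coefficients|`` approximates the instantaneous amplitude
    of a sinusoid at the matching frequency (unit sine -> ~1)."""

    freqs: np.ndarray
    coefficients: np.ndarray  # (n_samples, n_freqs) complex
    fs: float
    omega0: float = 6.0

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)


def cwt_morlet(x: np.ndarray, fs: float, f_lo: float, f_hi: float,
               n_freqs: int = 50, omega0: float = 6.0) -> WaveletSpectrum:
    """Complex Morlet wavelet transform on a log-spaced frequency vector.

    Implemented as an FFT-domain analytic Gaussian filter bank: at each
    center frequency f the positive-frequency spectrum is weighted by
    ``2 exp(-(s w - omega0)^2 / 2)`` with scale ``s = omega0 / (2 pi f)``,
    so a real cosine of amplitude A yields ``|W| ~ A`` at the matching
    frequency and ``angle(W)`` is its instantaneous phase (0 at peak).
    """
    x = np.asarray(x, dtype=float)
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi >= fs / 2:
        raise ValueError(f"f_hi={f_hi} must be below Nyquist ({fs / 2})")
    freqs = np.geomspace(f_lo, f_hi, n_freqs)
    n = x.shape[-1]
    nfft = sp_fft.next_fast_len(n)
    X = sp_fft.fft(x, nfft)
    w = 2 * np.pi * sp_fft.fftfreq(nfft, 1.0 / fs)
    pos = w > 0
    coefs = np.empty((n, n_freqs), dtype=complex)
    for k, f in enumerate(freqs):
        s = omega0 / (2 * np.pi * f)
        G = np.zeros(nfft)
        G[pos] = 2.0 * np.exp(-0.5 * (s * w[pos] - omega0) ** 2)
        coefs[:, k] = sp_fft.ifft(X * G)[:n]
    return WaveletSpectrum(freqs=freqs, coefficients=coefs, fs=fs, omega0=omega0)


# --------------------------------------------------------------------------
# band-averaged coherence matrix


def band_coherence_matrix(rec, band=(30.0, 100.0), state_intervals=None,
                          nperseg_s: float = 1.0, overlap: float = 0.5) -> np.ndarray:
    """Channel x channel magnitude-squared coherence averaged across a band.

    Welch cross-spectra on ``nperseg_s`` windows with fractional
    ``overlap``; only windows fully inside ``state_intervals`` contribute.
    Returns a symmetric matrix with unit diagonal, entries in [0, 1].
    """
    fs = rec.fs
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    nperseg = int(round(nperseg_s * fs))
    noverlap = int(round(nperseg * overlap))
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    fsel = (freqs >= band[0]) & (freqs <= band[1])
    if not fsel.any():
        raise ValueError("no FFT bins inside requested band")
    # channels processed in chunks: the full-spectrum frame array of a
    # 64-channel session would not fit comfortably in memory
    chunks = []
    t = None
    for i in range(0, rec.n_channels, 8):
        xi = rec.voltage_uv(channels=slice(i, min(i + 8, rec.n_channels)))
        _, t, Zi = welch_frames(xi, fs, nperseg, noverlap)
        chunks.append(Zi[:, fsel, :].astype(np.complex64))
    Zb = np.concatenate(chunks, axis=0)        # (ch, nf, frames)
    del chunks
    if state_intervals is not None:
        half = nperseg_s / 2
        keep = np.zeros(t.size, dtype=bool)
        total = 0.0
        for s, e, *_ in state_intervals:
            keep |= (t - half >= s) & (t + half <= e)
            total += e - s
        if total < 10.0 or not keep.any():
            raise ValueError("state intervals must total >= 10 s of data")
        Zb = Zb[..., keep]
    n_ch = rec.n_channels
    C = np.zeros((n_ch, n_ch))
    for fi in range(Zb.shape[1]):
        M = Zb[:, fi, :].astype(np.complex128)
        S = M @ M.conj().T / M.shape[1]
        auto = np.real(np.diag(S))
        denom = np.outer(auto, auto)
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(S) ** 2 / denom
        C += np.nan_to_num(coh, nan=0.0)
    C /= Zb.shape[1]
    C = np.clip((C + C.T) / 2, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


# --------------------------------------------------------------------------
# phase-amplitude coupling (modulation index)


@dataclass
class ModulationResult:
    MI: float
    phase_bin_centers: np.ndarray
    mean_amp_per_bin: np.ndarray     # normalized, sums to 1
    surrogate_p: float | None = None
    n_surrogates: int = 0


def modulation_index_from_phase_amp(phase: np.ndarray, amp: np.ndarray,
                                    n_bins: int = 20) -> ModulationResult:
    """Modulation index from paired phase / amplitude samples.

    MI = KL(P || uniform) / log(n_bins) where P is the normalized mean
    amplitude per phase bin; 0 for phase-independent amplitude, 1 when all
    amplitude concentrates in a single bin.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude must have equal length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=amp, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_amp = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = mean_amp.sum()
    if total <= 0:
        warnings.warn("all-zero amplitude; MI set to 0")
        P = np.full(n_bins, 1.0 / n_bins)
        return ModulationResult(0.0, centers, P)
    P = mean_amp / total
    nz = P > 0
    kl = float(np.sum(P[nz] * np.log(P[nz] * n_bins)))
    return ModulationResult(kl / np.log(n_bins), centers, P)


def modulation_index(phase_signal: np.ndarray, amp_signal: np.ndarray, fs: float,
                     phase_band=(1.0, 3.0), amp_band=(60.0, 100.0),
                     n_bins: int = 20, n_surrogates: int = 1000,
                     seed=None) -> ModulationResult:
    """Phase-amplitude coupling between two (possibly identical) signals.

    Phase of the band-passed phase signal and amplitude envelope of the
    band-passed amplitude signal are combined into the modulation index.
    Significance is assessed with circularly time-shifted surrogates
    (shifts uniform in [1 s, duration - 1 s]); surrogate_p is the fraction
    of surrogates with MI >= observed.
    """
    from scipy.signal import hilbert

    if len(phase_signal) != len(amp_signal):
        raise ValueError("signals must have equal length")
    ph = np.angle(hilbert(bandpass(phase_signal, fs, *phase_band)))
    am = envelope(bandpass(amp_signal, fs, *amp_band))
    res = modulation_index_from_phase_amp(ph, am, n_bins)
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        n = len(ph)
        lo, hi = int(fs), max(int(n - fs), int(fs) + 1)
        shifts = rng.integers(lo, hi, size=n_surrogates)
        mi_surr = np.empty(n_surrogates)
        for i, sh in enumerate(shifts):
            mi_surr[i] = modulation_index_from_phase_amp(ph, np.roll(am, int(sh)), n_bins).MI
        res.surrogate_p = float(np.mean(mi_surr >= res.MI))
        res.n_surrogates = n_surrogates
    return res


# --------------------------------------------------------------------------
# spike-phase coupling


@dataclass
class PhaseCouplingResult:
    freqs: np.ndarray
    R: np.ndarray                 # mean resultant length per frequency
    preferred_phase: np.ndarray   # circular mean per frequency, (-pi, pi]
    rayleigh_p: np.ndarray
    n_spikes: int
    preferred_freq: float | None  # argmax R among significant frequencies
    insufficient: bool = False

    def best(self):
        """(R, phase, p) at the preferred frequency, or None."""
        if self.preferred_freq is None:
            return None
        k = int(np.argmin(np.abs(self.freqs - self.preferred_freq)))
        return self.R[k], self.preferred_phase[k], self.rayleigh_p[k]


def resultant_length(phases: np.ndarray) -> float:
    """Mean resultant length R of a sample of angles."""
    if len(phases) == 0:
        return 0.0
    return float(np.abs(np.mean(np.exp(1j * np.asarray(phases)))))


def circular_mean(phases: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * np.asarray(phases)))))


def rayleigh_test(phases: np.ndarray) -> float:
    """Rayleigh test p-value for non-uniformity of circular data."""
    import pingouin as pg

    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        return 1.0
    _, p = pg.circ_rayleigh(phases)
    return float(p)


def spike_phase_coupling(spike_times: np.ndarray, lfp: np.ndarray, fs: float,
                         band=(30.0, 100.0), n_scales: int = 20,
                         intervals=None, alpha: float = 0.05,
                         omega0: float = 6.0) -> PhaseCouplingResult:
    """Per-frequency spike-LFP phase locking via Morlet wavelet phases.

    For each of ``n_scales`` log-spaced frequencies in ``band`` the wavelet
    phase at each spike time is collected; R (mean resultant length),
    circular mean phase and Rayleigh p are reported per frequency, and the
    preferred frequency is the R-argmax among significant (p < alpha)
    frequencies.  Results are flagged insufficient below 10 spikes.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if intervals is not None:
        from ._utils import in_intervals

        spike_times = spike_times[in_intervals(spike_times, intervals)]
    idx = np.clip(np.round(spike_times * fs).astype(int), 0, len(lfp) - 1)
    n_spk = idx.size
    freqs = np.geomspace(band[0], band[1], n_scales)
    if n_spk < 10:
        z = np.zeros(n_scales)
        return PhaseCouplingResult(freqs, z, z.copy(), np.ones(n_scales),
                                   n_spk, None, insufficient=True)
    spec = cwt_morlet(lfp, fs, band[0], band[1], n_scales, omega0=omega0)
    R = np.empty(n_scales)
    mu = np.empty(n_scales)
    pvals = np.empty(n_scales)
    for k in range(n_scales):
        ph = np.angle(spec.coefficients[idx, k])
        R[k] = resultant_length(ph)
        mu[k] = circular_mean(ph)
        pvals[k] = rayleigh_test(ph)
    sig = pvals < alpha
    preferred = float(freqs[np.argmax(np.where(sig, R, -1.0))]) if sig.any() else None
    return PhaseCouplingResult(freqs, R, mu, pvals, n_spk, preferred)


def spike_phase_coupling_matrix(spike_trains: dict, signals: np.ndarray, fs: float,
                                band=(30.0, 100.0), n_scales: int = 20,
                                alpha: float = 0.05, omega0: float = 6.0):
    """Spike phase coupling of many units against many reference signals.

    For each reference signal (e.g. each gamma IC) the Morlet phases at
    every unit's spike times are evaluated across ``n_scales`` log-spaced
    frequencies; the returned matrix holds each unit's mean resultant
    length at its per-signal preferred (R-argmax) frequency, zeroed where
    the Rayleigh test at that frequency is not significant (p >= alpha) or
    the unit has < 10 spikes.  Returns ``(R_matrix, pref_freq_matrix,
    p_matrix, unit_ids)`` with rows in sorted unit order.

    The transform is computed once per signal and frequency, so the cost
    is O(n_signals * n_scales) FFTs rather than per unit pair.
    """
    unit_ids = sorted(spike_trains)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_sig = signals.shape[0]
    freqs = np.geomspace(band[0], band[1], n_scales)
    idx = {u: np.clip(np.round(np.asarray(spike_trains[u]) * fs).astype(int),
                      0, signals.shape[1] - 1) for u in unit_ids}
    R = np.zeros((len(unit_ids), n_sig))
    P = np.ones((len(unit_ids), n_sig))
    F = np.full((len(unit_ids), n_sig), np.nan)
    for j in range(n_sig):
        spec = cwt_morlet(signals[j], fs, band[0], band[1], n_scales, omega0=omega0)
        r_uf = np.zeros((len(unit_ids), n_scales))
        for k in range(n_scales):
            ph_all = np.angle(spec.coefficients[:, k])
            for ui, u in enumerate(unit_ids):
                if idx[u].size >= 10:
                    r_uf[ui, k] = resultant_length(ph_all[idx[u]])
        for ui, u in enumerate(unit_ids):
            if idx[u].size < 10:
                continue
            k = int(np.argmax(r_uf[ui]))
            ph = np.angle(spec.coefficients[idx[u], k])
            p = rayleigh_test(ph)
            F[ui, j] = freqs[k]
            P[ui, j] = p
            if p < alpha:
                R[ui, j] = r_uf[ui, k]
    return R, F, P, unit_ids


# --------------------------------------------------------------------------
# mean-subtracted depth spectra


def mean_subtracted_spectrum(rec, state_intervals=None, f_lo: float = 0.5,
                             f_hi: float = 100.0, nperseg_s: float = 2.0):
    """Depth x frequency power map with the across-channel mean removed.

    Per-channel Welch power (dB) within the given intervals, minus the mean
    across channels at each frequency: the output sums to ~0 across
    channels per frequency, highlighting depth-specific power.
    Returns (freqs, map) with map shaped (n_channels, n_freqs).
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    mask = (sample_mask(rec.n_samples, rec.fs, state_intervals)
            if state_intervals is not None else slice(None))
    nperseg = int(round(nperseg_s * rec.fs))
    rows = []
    freqs = None
    for i in range(0, rec.n_channels, 8):
        xi = rec.voltage_uv(channels=slice(i, min(i + 8, rec.n_channels)))
        xi = xi[:, mask]
        freqs, _, Z = welch_frames(xi, rec.fs, nperseg, nperseg // 2)
        rows.append(np.mean(np.abs(Z) ** 2, axis=-1))
    power = np.concatenate(rows, axis=0)
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    logp = 10 * np.log10(np.maximum(power[:, sel], 1e-300))
    return freqs[sel], logp - logp.mean(axis=0, keepdims=True)
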