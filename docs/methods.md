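# Methods

`laminarkit` analyzes single-shank laminar silicon-probe recordings from
cortex: continuous multichannel LFP plus sorted spike trains. This note
describes the models and procedures, the choices made where the design was
genuinely open, what the synthetic-data generator does and does not
emulate, and the numerical details a user reproducing results will care
about. Problem sizes quoted below are the ones the test suite and
`scripts/acceptance.py` use.

## Conventions

Times are seconds from recording start, intervals half-open `[start, end)`.
Depths are micrometres, zero at the shallowest site, increasing downward;
the estimated pia lies 80 µm above landmark *a*. Continuous voltage is
stored channels × time as int16 ADC counts with a µV scale factor
(Neuroscope-style flat binary; `.dat` wideband at 20 kHz, `.lfp` at
1.25 kHz after zero-phase FIR anti-aliasing and decimation). Oscillation
phase is 0 at the peak and ±π at the trough, increasing with time — the
angle of an analytic (positive-frequency) transform of a cosine.

## Physiological landmarks and depth normalization

Five depth anchors make sessions comparable across animals:

- **c** — the maximum of the 500 Hz–5 kHz power profile (aggregate spiking
  of large layer-5 pyramidal cells, mid layer 5). Requires wideband data;
  when only LFP is available the pipeline falls back to the 100–400 Hz
  power profile, which tracks the same spiking "hash".
- **a, b, d, e** — the prominent sources (a, e) and sinks (b, d) of the
  current source density (CSD) of the DOWN→UP transition of non-REM slow
  oscillation. CSD is the negative second spatial difference of the
  event-triggered LFP average, `-(V[i-1] - 2V[i] + V[i+1])/Δz²`, sinks
  negative, conductivity 1 (relative units), outermost channels undefined.

The landmark profile is read at the transition's dominant-energy time
slice (±10 ms) rather than from per-channel extremes across the whole
0–150 ms window: successive delta waves have opposite polarity, and
per-channel extremes would mix neighbouring events (this displaced
superficial landmarks by >200 µm in testing). Prominence is peak absolute
amplitude; the ordering a < b < c < d < e is enforced and a violation is
an error carrying the diagnostic profile.

Depth normalization is a piecewise-linear warp that maps each recovered
landmark exactly onto its canonical depth, stretching the stretches in
between, with linear extrapolation beyond *a* and *e*. The warp is
monotone and exactly invertible.

## Gamma coherence clustering

Pairwise 30–100 Hz magnitude-squared coherence between all sites (Welch
cross-spectra, 1 s Hann windows, 50% overlap, band-averaged; only windows
fully inside the requested brain-state intervals contribute) yields a
64×64 similarity matrix `C`. Sites are partitioned by descending the
interaction energy

    E_A = -(1/N_A) * Σ_{i≠j∈A} C_ij ,    E_total = Σ_A E_A

The diagonal (self-coherence) is excluded: including it adds a constant
`1/N_A` bias toward large clusters. From a random assignment into (up to)
10 groups, sites are visited in seeded random order and moved to whichever
cluster — including a fresh singleton — most lowers the *exact* total
energy; when no single-site move helps, whole-cluster merges are tried,
and descent resumes until neither move kind lowers the energy. Moves are
evaluated by the exact energy difference rather than a first-order
coherence-gain gap: this guarantees monotone descent of `E_total`,
terminates at a genuine local minimum with respect to both move kinds, and
(merge moves especially) escapes the fragmented local minima that
site-moves alone cannot leave. The cluster count is emergent, not fixed.
Because initialization and visit order are stochastic, the descent is
restarted (default 50; 8–20 in the test workloads), the modal converged
partition is reported, and a consistency score (mean adjusted Rand index
of each restart against the modal solution) quantifies stability. On
exhaustive enumeration of all 203 partitions of six sites, the restarted
descent finds the global minimum in >80% of random matrices.

## Gamma ICA

Band-passed (30–100 Hz) channel signals are reduced to 10 principal
components and unmixed with FastICA (up to 5 re-seeded retries, tolerance
1e-3; the components beyond the true source count are noise-dominated and
converge slowly, which is why the tolerance is not tighter). Channel-space
loadings are the PCA back-projection of the mixing matrix, sign-fixed so
each loading's maximum-absolute element is positive, and components are
ranked by explained variance. Because ICs are not exactly orthogonal, raw
back-projection variances need not sum below the total; shares are
normalized within the PCA reconstruction and scaled by the PCA-captured
fraction, so they sum to ≤ 1 by construction. A component whose loading
has coefficient of variation < 0.1 is flagged as volume-conducted and
excluded from the six laminar components; its relative power estimates the
volume-conducted share of gamma-band variance (recovered ≈ 0.33 on
sessions generated with a 0.34 share).

## Spectral substrate

The Morlet continuous wavelet transform is implemented as an FFT-domain
analytic Gaussian filter bank with ω₀ = 6 on log-spaced frequencies,
normalized so a unit-amplitude cosine yields |W| ≈ 1 at the matching
frequency and `angle(W)` is its instantaneous phase under the peak-zero
convention.

Phase-amplitude coupling uses the modulation index: the amplitude envelope
of the fast band is averaged in 20 phase bins (18°) of the slow band's
phase, the bin distribution normalized to sum 1, and MI is its KL
divergence from uniform divided by `log 20`, so MI ∈ [0, 1], exactly 0 for
phase-independent amplitude and 1 when all amplitude falls in one bin.
Significance comes from 1000 circular time-shift surrogates (shifts
uniform in [1 s, duration − 1 s], seeded); the p-value is the fraction of
surrogates with MI at least the observed. Note that time-shift surrogates
are only a valid null when the slow phase drifts (narrowband noise); a
perfectly periodic carrier is invariant under shifts.

Spike-LFP coupling evaluates the wavelet phase at each spike time across
20 log-spaced frequencies in 30–100 Hz; per frequency the mean resultant
length R, circular mean phase, and Rayleigh p (via pingouin) are reported,
and the preferred frequency is the R-argmax among significant (p < 0.05)
frequencies. Fewer than 10 spikes flags the result insufficient. For the
unit × IC coupling matrix the transform is computed once per IC and
frequency (not per unit), entries are R at the per-unit preferred
frequency, zeroed where the Rayleigh test fails.

## Brain-state scoring

Three per-second traces are computed from a representative channel
(default 55% depth, near landmark c): PC1 of the z-scored log spectrogram
(10 s windows sliding by 1 s, truncated at the edges, 100 log-spaced
frequencies 1–100 Hz; sign-oriented so frames with high sub-20 Hz power
are positive), the theta ratio (5–10 Hz over 2–16 Hz power), and an EMG
proxy (mean zero-lag pairwise correlation of 300–600 Hz band-passed
signals across up to 8 sites — muscle activity is volume-conducted and
coherent across the whole probe, brain high-frequency activity is not).

Divisions are made at the trough between the two largest modes of each
trace's kernel density estimate (Gaussian KDE, Silverman-type bandwidth;
the density is zero-padded so modes at the range edges count). The trough
must lie below half the smaller peak's density — a shallow trough (e.g.
the continuous variation of oscillation bouts within waking) is not a
state boundary, and no division is made (with a warning) unless the user
supplies a fixed threshold. NREM is frames above the PC1 trough; among the
rest, REM requires EMG below its trough and theta above its trough;
everything else is waking. Labels are smoothed with a 5-frame majority
filter. Waking bouts shorter than 7 minutes are merged into the flanking
sleep state (the longer neighbour wins) and reported as merged arousals.
On a 30-minute synthetic three-state session, per-frame accuracy is
~99.5%; residual errors sit at state transitions where the 10 s window
straddles two states.

## DOWN/UP detection

DOWN states are coincident excursions of two signals from the detection
channel within non-REM: a peak of the 0.5–8 Hz (zero-phase 4th-order
Butterworth) delta trace, and a drop of the 100–400 Hz power (RMS smoothed
in an 80 ms window, log-scaled), both z-scored within NREM. For each
signal, candidate excursions beyond 0.25 SD are binned by magnitude in
fixed 0.25 SD bins (fixed-width, not quantiles: sparse noise peaks and
dense true events must not share a bin); the peak threshold is the lower
edge of the smallest bin (≥5 events) whose population-spike rate at the
excursion peak falls below 0.2× the mean rate, and the window threshold
(which sets event boundaries) is the mean signal value at the
rate-recovery time across qualifying bins, capped at half the peak
threshold so the crossing of the smoothed signal lands at the event edge
rather than inside it. Candidate events from each signal are limited to
≥40 ms, DOWN events are their overlaps (again ≥40 ms, ≤1 s), and UP states
are the gaps between DOWNs inside NREM. Raising the rate criterion only
adds magnitude bins, so the event count is monotone in it. Median boundary
error against planted DOWN states is ~10 ms, and 30 ms planted DOWN states
are rejected by the 40 ms floor.

## Unit classification and statistics

- **Waveform**: positive-polarity units are set aside; fiber volleys are
  negative-waveform units whose normalized-waveform second-derivative
  kurtosis exceeds 5 SD of the population mean. The literal mean/SD rule
  is the default: a median/MAD variant is available but collapses on the
  (bimodal) kurtosis distribution of a healthy E/I population and
  mislabels every narrow waveform, and the mean/SD rule cannot flag
  anything at 5 SD below n ≈ 27 anyway (the largest z in a sample of n is
  (n−1)/√n). Remaining units split at 0.55 ms trough-to-peak latency:
  wide = putative excitatory (E), narrow = putative interneuron (I).
- **CCG identity**: a unit with an outgoing excitatory (inhibitory) edge
  is CCG-E (CCG-I); both kinds flags it ambiguous.
- **Optotagging**: tagged if the mean of the two largest 1 ms bins in the
  1–6 ms post-pulse histogram exceeds the −100–0 ms baseline mean by 8
  baseline SD (≥100 pulses; a silent baseline degenerates to "any response
  spikes", flagged).
- **Burst index**: mean autocorrelogram count at 1.5–13.5 ms over mean
  count at 200–300 ms (0.5 ms bins, zero-lag excluded); ≈1 for Poisson
  trains, ≈0 for refractory regular trains; the coarser 3–10 ms numerator
  is available as an argument.
- **UP-state dynamics**: peri-onset histogram at 10 ms bins; the
  transient/steady ratio divides the 0–200 ms peak rate by the 100–200 ms
  mean rate (the windows overlap by construction — implemented literally);
  first-spike latency is the median over transitions, censored at 500 ms.
- **DOWN-active detection**: per-event DOWN vs UP rates compared by
  Wilcoxon rank-sum; flagged iff the median DOWN rate exceeds the median
  UP rate and p < α. The two-sided test plus the direction condition keeps
  the null flag rate at ≈ α/2.
- **Coupling clusters**: the unit × IC matrix of R values is clustered
  with cityblock k-means (Lloyd iterations with per-coordinate median
  update, 10 seeded restarts — no installed library offers an L1 k-means),
  K ∈ 2..12 chosen by maximum mean silhouette (cityblock metric).
  Identical profiles return a flagged single cluster.

## Monosynaptic connectivity

Cross-correlograms use 0.5 ms bins over ±50 ms with bin edges on the
0.5 ms grid, so the (+1.5, +4] ms monosynaptic window is exactly the five
bins centered 1.75–3.75 ms. Per-state CCGs restrict both trains to the
state's intervals and count pairs per interval, so lags never span
interval boundaries; for autocorrelation-style inputs identical-index
pairs are removed.

The baseline predictor convolves the CCG with a unit-area 7 ms-SD
Gaussian (reflected edges; total count preserved). Significance per bin is
the exact Poisson tail at the predicted rate: `k_hi` is the smallest count
with CDF ≥ 0.999999 and `k_lo` the largest with CDF ≤ 1e-6 (exact CDF, no
normal approximation; verified against 60-digit term-by-term summation —
for λ = 1, `k_hi` = 9). An excitatory edge needs ≥2 consecutive window
bins strictly above `k_hi`; an inhibitory edge ≥2 consecutive bins
strictly below `k_lo` (the symmetric lower tail at the same level — note
a trough is only detectable when the expected bin count is large enough
that the lower bound is positive, i.e. for high-rate pairs or long
recordings). Both present reports both, flagged. Under the null
(independent Poisson pairs) the empirical false-edge rate is 0 per 10⁴
pairs.

Spike transmission probability is the summed excess count over the window
per presynaptic spike. Detection uses the plain predictor, but the
*estimate* uses a hollowed predictor (window bins linearly interpolated
across before convolving): the plain convolution counts ~15–25% of the
peak into its own baseline and biases the estimate low by that amount,
while the hollowed estimate recovers planted probabilities of 0.05–0.2
within ~±10%. The peak-to-baseline ratio (max window count over mean
window predictor) is reported alongside. State-dependent transmission
recomputes CCG and predictor within each state (≥500 presynaptic spikes
required, otherwise excluded) and compares paired per-edge values across
states with the Wilcoxon signed-rank test. The fuller model-based
correction of transmission estimates for slow comodulation is a documented
extension point, not implemented.

## Synthetic sessions

The generator is first-class, tested code: it defines the conditions every
recovery claim is made under. A session is a deterministic function of its
config (bit-identical across runs, seed included).

**LFP.** Six gamma sources (30–100 Hz band-limited noise, each with an
independent slow lognormal burst envelope — exponent clipped at ±2.5 SD so
burst power spans about an order of magnitude; an unclipped envelope lets
a single burst carry nearly all session variance, which is both
unphysiological and fatal to any coherence estimate) with flat-top
generalized-Gaussian depth loadings (exponent 6, width 0.45× layer
thickness, unit maximum). Flat-top rather than Gaussian: a layer generates
gamma throughout its extent and coherence drops sharply at boundaries;
Gaussian loadings either leave mid-layer-gap channels dominated by volume
conduction or mix 50/50 at boundaries, and in both cases a spurious
seventh cluster appears. The burstiness (super-Gaussianity) is what makes
the mixture separable by ICA — band-limited *Gaussian* noise would not be.
A spatially uniform broadband gamma source models volume conduction,
scaled to a configurable share (default 0.34) of gamma-band variance.
Slow oscillation: alternating UP (lognormal durations, median 0.9 s) and
DOWN (gamma-distributed, mode 50–150 ms) epochs at ~0.55 DOWN/s within
NREM; each DOWN carries a delta wave (Hann bump slightly outlasting the
DOWN, in proportion to it) and each DOWN→UP transition a 120 ms wave whose
CSD equals the planted landmark dipole pattern — the depth profile solves
the discrete Poisson equation for the target CSD with a grounded top and
zero-gradient bottom, so the second-difference estimator recovers the
planted sinks/sources exactly and deep channels keep the large slow-wave
amplitude of deep layers. Waking adds a 3–6 Hz rhythm (bouts of
immobility, largest at layer 4) and a common 300–600 Hz "EMG" term; REM
adds spatially uniform theta. A 100–400 Hz per-channel hash whose envelope
collapses during DOWN states stands in for aggregate spiking, and
independent white (5 µV) plus 1/f (15 µV RMS) background noise completes
the signal — the 1/f floor matters: with white noise only, waking
low-frequency power is near-binary across rhythm bouts and any
quantile-free state scorer will split it.

**Spikes.** Lognormal rates (median 3 Hz, σ = 0.8, interneurons 2×),
state-dependent rate factors (deep units 2× waking/NREM), DOWN silencing
to 2%, von Mises phase coupling to the unit's layer gamma source and to
the waking rhythm (κ solved from the target mean resultant length, so the
planted R is exact in expectation), and bimodal trough-to-peak waveform
latencies (difference-of-Gaussians templates; I ≈ 0.30 ms, E ≈ 0.85 ms, so
the 0.55 ms boundary separates classes by construction). DOWN-active
units (35.2 Hz in DOWN, 4.3 Hz in UP — the defining rates of that class)
are off by default: they are ~0.3% of real populations, and a planted one
is a huge fraction of a 20–40 unit session's DOWN-epoch firing, which
would (correctly) defeat the population-silence calibration of the
slow-wave detector; analyses of DOWN-active units enable them explicitly.
Monosynaptic couplings are realized by injection (excitatory: each
presynaptic spike adds a postsynaptic spike with probability p at a lag
uniform in 1.5–4 ms, so the expected excess per presynaptic spike equals p
exactly) or thinning (inhibitory). Optotagging adds light pulses and
injected short-latency responses for tagged units.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biophysical (conductance/compartment) realism,
receptive fields and visually evoked dynamics, electrode drift and sorting
errors, non-stationary state transitions (states switch instantaneously),
spatially correlated noise, and the co-fluctuation of rate and synaptic
efficacy that motivates corrected transmission estimators. Wideband is
generated only as a short snippet with the mid-layer-5 power bump (the
depth profile needs seconds, not a full session at 20 kHz).

## Problem sizes

Layer recovery runs on one 600 s, 64-channel waking session; state scoring
on a 30-minute three-state session plus a separate session with a planted
5-minute arousal; slow-wave metrics on 600 s of NREM (plus a 300 s
all-30 ms-DOWN session); connectivity on a 20-unit, 600 s network with
planted probabilities {0.05, 0.1, 0.2} and 10⁴ independent null pairs; the
descent-vs-enumeration check on 500 random six-site matrices. These sizes
put every estimate comfortably past its own convergence regime (e.g.
≥3000 presynaptic spikes per tested edge) while keeping the whole suite
desk-scale.

## Known limitations

Coherence clustering assumes the probe spans the layered structure; on a
probe confined to one layer the emergent count is 1–2, not 6. The
state scorer's data-driven thresholds need every scored state to occupy
enough frames to form a mode; sessions missing a state entirely are
handled (no division), but a state present for only a few frames will be
absorbed. Inhibitory-edge detection at the 1e-6 per-bin level is
structurally insensitive for low-rate pairs. The depth warp is only as
good as the landmarks; it propagates, not corrects, a misplaced landmark.
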