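# Methods

This note documents the models, conventions and numerical choices behind
`thetasort`, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Signal model and units

A recording is a channels × samples matrix in microvolts at a single
sampling rate (default 24,414 Hz; a 20,000 Hz preset is used for
desk-scale simulations). Time is in seconds, zero-based at recording
start; sample *s* sits at time *s*/rate. On disk a recording is a flat
little-endian float32 binary (channel-major) with a JSON sidecar
declaring rate, channel ids, region tags and the µV scale — float32
payloads round-trip bit-exactly. Events and spike tables are
tab-separated UTF-8 text with one header line.

## Filtering

All filters are 4th-order Butterworth designs in second-order sections,
applied forward–backward (`sosfiltfilt`) with reflective padding of
about three impulse-response lengths of the low band edge. Zero net
phase is mandatory: spike phases are read off the filtered theta trace
sample-by-sample, so any group delay would bias every phase estimate.
Named bands: LFP 0.1–300 Hz, spike 500–3000 Hz (default for sorting),
wide spike 300–6000 Hz, theta 4–8 Hz. The 60 Hz notch is an IIR notch
of quality factor 30, also applied forward–backward; it attenuates a
pure 60 Hz tone by more than 20 dB while passing 6 Hz and 1 kHz tones
within 1 dB.

**Phase convention.** Instantaneous phase is the angle of the analytic
(Hilbert) signal of the theta-filtered trace, mapped to [0°, 360°):
0° at the positive theta peak, increasing with time. Phase lookup at a
spike time is nearest-sample; at ≥ 20 kHz sampling and ≤ 8 Hz theta the
lookup error is below 0.15°, so interpolation is not worth its
complexity.

## Detection and sorting

The detection threshold is −5 × the plain standard deviation of the
entire spike-band-filtered trace. A median-based robust noise estimate
(|x|-median / 0.6745) is available behind a flag but off by default,
keeping the stated rule exact. Detection is negative-going only. Each
downward crossing is refined to the local minimum within ±0.5 ms, and
crossings within a 1 ms dead time of the previous accepted spike are
suppressed. A constant trace (SD = 0) returns an empty train rather
than erroring.

Snippets span 0.8 ms before to 1.6 ms after the trough (configurable),
trough at the alignment index. Re-alignment searches ±2 samples around
the nominal index; for ground-truth spike times (already trough-exact)
re-alignment can be disabled, because selecting the minimum of noisy
samples systematically deepens the trough estimate at low SNR.

Features are the projections onto the top 8 principal components of the
mean-centered snippet matrix; each axis's sign is fixed so its
largest-magnitude loading is positive, making feature snapshots
reproducible. Clustering is k-means with a seeded generator and 10
restarts, keeping the partition with minimal within-cluster sum of
squares; *k* is user-specified per channel (a silhouette-based
suggestion utility exists but is never auto-applied).

**SNR** is the rms over ±1 ms windows around spike times divided by the
rms of all remaining samples, making it scale-invariant.

## Cluster quality

Squared Mahalanobis distances use the cluster's own mean and unbiased
covariance; computing them requires N_c > d. A ridge of
1e-9 · trace(Σ)/d is added only when the condition number exceeds 1e12 —
a guard for degenerate synthetic fixtures, never on the mathematical
path for realistic data. "Noise spikes" for a cluster are all other
spikes detected on the same channel, whether assigned to another
cluster or unassigned. The L-ratio sums 1 − CDF_χ²(MD², df) over those
noise spikes and divides by N_c, with df equal to the feature dimension
actually used (8 by default, not hard-coded). The isolation distance is
the N_c-th smallest non-member MD²; when fewer than N_c non-members
exist it is reported as an explicit undefined flag, not an error — the
common case for a dominant cluster on its own channel.

## Circular statistics

Circular mean and resultant length follow the standard vector-sum
definitions. The Rayleigh statistic is z = nR̄², with the classical
series approximation

p = exp(−z)·[1 + (2z − z²)/(4n) − (24z − 132z² + 76z³ − 9z⁴)/(288n²)]

clamped to (0, 1]. Type-I calibration is verified empirically (rejection
rate in [0.03, 0.07] at nominal 0.05 over 1000 uniform samples of
n = 100). Units with fewer than 25 spikes are reported with
`included=False` and no test statistics; the boundary is inclusive
(n = 25 qualifies). For exactly balanced samples (R̄ = 0) the circular
mean is undefined and returned as None.

Theta propagation delay between channels is the lag maximizing the
normalized cross-correlation within ±max_lag, computed by one FFT
correlation pass with per-lag normalization from cumulative sums.
Because theta is narrowband, delays are only unambiguous well inside
one period; the default ±50 ms window respects that.

## Behavioral statistics

Epochs are half-open [start, end): a spike exactly at an epoch boundary
belongs to the following epoch, so epochs partition time without double
counting. Spikes outside all epochs are tallied under "unassigned", and
epoch counts plus unassigned always equal the total. Turn bias is the
per-trial left fraction n_L/(n_L+n_R), averaged over paired trials;
empty trials are excluded and counted. The LFP trend slope is an
ordinary least-squares line over the epoch's samples. Recording yield is
round(100 · sortable/channels) half-away-from-zero, so 5 of 12 prints
as 42%.

## Session tracking and amplitude estimation

Chronic tracking follows, per session: the mean unit amplitude, the
yield, and each unit's mean waveform normalized to its maximum absolute
value, compared with the unit's first appearance by Pearson correlation
(normalization makes the similarity scale-free by construction).

Amplitude uses a template-anchored estimator: the extremal sample
indices are located on the unit's full mean waveform (noise averaged
down), then trough-to-peak differences are read at those two fixed
indices from 10 randomly sampled spikes and averaged. The naive
max-minus-min of individual noisy snippets is strongly biased upward at
low amplitude — for a 24 µV unit on 15 µV broadband noise it
overestimates by ~40%, because the noise's own range dominates the
window — while reading at fixed indices keeps the noise contribution
zero-mean. Session amplitude recovery across a [24, 143, 125] µV
trajectory lands within a few percent of truth with this estimator
(verified in the acceptance suite at 12 channels × 20 s per session,
20 kHz, the package's default desk-scale problem size for chronic
series). Amplitude tracking measures in the wide 300–6000 Hz band,
which passes the template nearly unattenuated; the narrow sorting band
clips ~11% of peak-to-peak.

## The synthetic generator

The generator produces the statistical structure the analysis assumes,
with defaults chosen to mirror the recording conditions the pipeline
targets:

* **LFP**: theta sinusoid, frequency 6 Hz (valid range 4–8 Hz), default
  amplitude 150 µV, optional per-channel propagation delay; pink
  (1/√f-shaped) background confined below 300 Hz (default 20 µV rms) so
  it perturbs LFP analysis but not spike detection; optional 60 Hz
  mains sine.
* **Noise**: white Gaussian noise whose *broadband* rms is the
  configured `noise_rms` (default 15 µV). Its rms inside the 500–3000 Hz
  sorting band is then ≈ 6.4 µV at 24,414 Hz (the band carries
  √(B_eff/Nyquist) of the power); tests assert the band-limited value
  measured by filtering a long white-noise run, not the broadband one.
* **Units**: inhomogeneous Poisson spike trains by thinning with
  intensity λ(t) = base_rate · state_gain(epoch(t)) ·
  exp(κ·cos(φ(t)−μ))/I₀(κ). The I₀ division normalizes the phase factor
  to average 1 over a uniform phase cycle, so the time-average rate is
  base_rate · gain exactly (up to the small refractory loss). The
  thinning envelope is base·max(gain)·e^κ/I₀(κ). The absolute
  refractory period (default 2 ms) is enforced by deleting violating
  spikes, not by hazard reshaping — simple and exact for validation
  purposes.
* **Templates**: a negative Gaussian trough (FWHM = trough width,
  default 0.3 ms) followed by a 0.4-relative positive rebound
  (default FWHM 0.6 ms), scaled to the requested peak-to-peak and
  rolled so the trough sits exactly at the alignment index.
* **Sessions**: one recording per week with all unit amplitudes set by
  the trajectory (default anchors 24 → 143 → 125 µV across weeks
  1 → 15 → 33, the dip-and-recovery shape typical of chronic implants),
  template shape held fixed (same neuron), and a per-week sortable
  channel schedule (week-one default 5 of 12 channels, i.e. 42% yield).

What it does **not** emulate: electrode drift and motion artifacts,
overlapping-spike collisions, bursting with amplitude adaptation,
non-stationary noise, biophysical (conductance-based) waveform
diversity, or impedance/thermal electrode noise. Passing recovery tests
therefore demonstrates correctness of the analysis chain under the
stated generative assumptions — not robustness to every pathology of
in-vivo data.

## Determinism

Every stochastic step takes a seed. The pipeline's single config seed
fans out to per-stage child seeds via
`SeedSequence([seed, stage_index])` (kept below 2³¹), so stages can be
rerun in isolation; rerunning the pipeline with the same config and
seed reproduces `summary.json` byte for byte.

## Problem sizes

Default validation sizes were chosen to be desk-scale while keeping
statistical power: 120 s two-channel recordings at 24,414 Hz for
end-to-end sorting/phase recovery, 20 s × 12 channels × 3 sessions at
20,000 Hz for chronic tracking, 1000 replicates of n = 100 for Rayleigh
calibration, and 500-point 8-D clusters for the separation criterion.

## Known limitations

* Detection is one-sided (negative); positive-going spikes are out of
  scope by design.
* k must be supplied per channel; no automatic model selection is
  applied.
* At amplitudes near the detection threshold (e.g. 60 µV peak-to-peak
  on 15 µV broadband noise in the narrow band), recall is partial and
  cluster contamination statistics honestly degrade — see the README's
  worked example.
* The L-ratio/isolation-distance machinery requires N_c > d; very small
  clusters are rejected with an explicit error.
* Theta delay estimates are meaningful only for lags well inside one
  theta period.
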