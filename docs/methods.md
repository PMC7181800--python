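# Methods

This note documents the models, estimators, numerical choices and known
limitations of `ripplepath`. Times are seconds, 0-based sample indexing,
half-open intervals `[start, stop)`; amplitude calibration of recordings is
treated as opaque (relative units). The phase convention everywhere is
peak = 0, trough = ±π, recorded in output metadata.

## Synthetic sessions

`ripplepath.synth.generate_session` emulates a dual-region awake recording;
it exists because the phenomenon's raw data are not deposited, and it is the
ground truth every analysis stage is scored against.

**LFP.** Each channel is unit-variance 1/f (pink) noise, chosen so that
SD-based detection thresholds are stressed by realistic low-frequency
content. CA1 ripples are Hann-enveloped sinusoids at `ripple_freq`
(default 170 Hz, inside the 140–200 Hz band) riding on negative Gaussian
sharp waves (σ = 15 ms). `ripple_duration_ms` (default 26 ms, matching the
reported median event duration) is interpreted as the envelope's full width
at half maximum — the *detectable* duration — so the Hann support spans
twice that; at 170 Hz this yields the reported ~5 cycles. Event times are
Poisson at `ca1_ripple_rate` (default 0.68 Hz, the reported CA1 incidence)
with a 150 ms refractory gap so planted events remain resolvable.
`ripple_snr` is the ripple peak amplitude over the broadband noise SD.
Each event propagates to gRSC with probability `propagation_prob`
(default 0.4, roughly the ratio of gRSC to CA1 ripple counts in the
modelled preparation) at `propagation_delay_ms` (default 5 ms, near the
reported ~4.8 ms median) with 1 ms jitter; gRSC amplitude is proportional
to CA1 amplitude with lognormal scatter, so power-coupling statistics have
planted structure. The gRSC stack spans 8 channels: the negative wave
scales from +1 (superficial) to −0.5 (deep) — the reported polarity
reversal — while the ripple rides only on the superficial half.

**Spikes.** Inhomogeneous Poisson trains (inverse-CDF sampling) with an
absolute refractory period (2.5 ms), so high-rate units survive the
ISI-violation QC as real units do. Rates gain multiplicatively inside
ripple windows (pyramidal default ×5) and are von Mises phase-modulated,
`exp(κ cos(φ − φ_pref))/I₀(κ)`, which preserves mean rate and gives the
analytic ITPC target I₁(κ)/I₀(κ). gRSC deep units are mildly suppressed
(×0.7) rather than driven, mirroring the laminar contrast.

**State.** Synchronized and desynchronized epochs alternate with
exponential dwells (mean 25 s, minimum 5 s). In synchronized epochs the
cortical population rate is a train of Gaussian packet bumps (3.5 Hz,
σ = 20 ms, peak gain ×4) over a near-silent floor (×0.01); desynchronized
epochs are tonic. gRSC unit rates default to 15 Hz so the pooled
32-unit population (~480 Hz) makes the state index cleanly bimodal: tonic
firing keeps 1 ms bins occupied while packet troughs force zeros. This is
the one place the generator leans on a fairly high per-unit rate; with
sparse populations the SI contrast of real MUA (which includes unsorted
spikes) would need hash-population augmentation. Desynchronized epochs
alternate a high/low EMG label; a shared 300–600 Hz band-passed source is
added to all channels with amplitude 0.6 SD (high-EMG) vs 0.05 (otherwise).

**Ripple types.** `plant_ripple_types` assigns each of `n_ripple_types` a
preferred unit subset (round-robin) boosted by `exp(separation)` with mild
lognormal jitter; `separation = 0` collapses all templates (clustering at
chance). Separation 2.5 is the "well-separated" regime in which k-means
recovery is essentially perfect (ARI ≈ 1); the library default 1.5 leaves
types present but noisy, which is the more realistic condition.
`grsc_type_coupling` gives superficial gRSC units type-specific lognormal
gain offsets, planting downstream discriminability.

What the generator does **not** model: biophysical membrane dynamics,
volume conduction beyond per-channel scaling, probe geometry, behavioural
covariates, spike sorting errors, non-stationary noise. Passing tests
demonstrate correctness of the estimators against planted structure, not
performance on any specific real dataset.

## Detection

Ripples: zero-phase (forward–backward) 2nd-order Butterworth at
100–280 Hz; rectified; Savitzky–Golay smoothing (11 ms window, order 2;
the window length is a package choice, exposed in config). Events require the smoothed envelope > mean + 2 SD *and* the
filtered trace > mean + 4 SD within the event, for ≥ 20 ms; of two events
with peaks < 40 ms apart the smaller-amplitude one is discarded, applied to
exhaustion (idempotent, order-independent). Means and SDs are taken over
the whole trace (single pass, no iterative re-estimation), which keeps
detection exactly invariant to rescaling. Onset/offset are the 2 SD
envelope crossings; sessions with < 100 events are flagged by
`RippleParams.min_events_for_session` for exclusion from summaries.

Negative waves: matched filter with a zero-mean, unit-norm template;
events at local maxima of the output above 1 × its RMS; the event peak is
the most negative trace sample in the template window, and matches whose
trough is non-negative are rejected as sidelobes (this is what makes
detection polarity-sensitive). The default template is session-adaptive:
the mean of the 50 largest low-pass (< 30 Hz) negative deflections —
a hand-curated clinical template is not reproducible.

Packets: detected on the Gaussian-smoothed (SD 30 ms) pooled population
rate, requiring ≥ 16 units. Local maxima must exceed the centred 10 s
local average by ≥ 60 % for ≥ 25 ms and be flanked within 1 s on both
sides by ≥ 25 ms troughs below 20 % of the local average; packets closer
than 15 ms merge. The minimum packet duration defaults to 25 ms; an
alternative 40 ms definition is also in circulation, and both are config
options. All criteria are ratios to the local average, so
detection is invariant to rate rescaling. Near regime boundaries the 10 s
local average is transitional and edge packets can be missed; scoring in
tests therefore uses interior events.

## Spectral estimators

Morlet wavelets use cycle counts log-interpolated from 3 to 12 across the
fixed 2–500 Hz anchor band (so a given frequency always gets the same
wavelet regardless of the requested grid) and are normalized to unit gain
for a real sine at the centre frequency. Event-triggered spectrograms are
z-scored per frequency against a baseline window ending ≥ 100 ms before
the event. The spike–field coherence tapers ±100 ms windows around event
peaks with 5 DPSS tapers (time–bandwidth 3) and averages cross/auto spectra
over tapers and events.

ITPC is the modulus of the mean unit phasor; the Rayleigh p-value uses the
standard finite-n corrected approximation (cross-checked against an
independent implementation in the tests). The significance rule for phase
preference is p < 0.05 ∧ ITPC > 0.1, evaluated at the ripple trough point.

PAC uses the KL-based modulation index over 50 phase bins (defaults: 39
log-spaced phase frequencies 2–40 Hz, 91 amplitude frequencies 50–500 Hz).
Entropy uses the 0·log 0 = 0 convention, so MI is exact on degenerate
inputs (all amplitude in one bin → MI = 1 exactly) without an ε floor.
Significance uses 200 circularly time-shifted amplitude surrogates (shifts
uniform in [1 s, T − 1 s]). The surrogate z-score (P_z) is reported, but
the masking p-value is the empirical surrogate percentile: the MI null is
right-skewed and the normal tail on P_z was measured to reject ~8 % of
white-noise nulls at a nominal 5 %, whereas the rank-based p is calibrated.
MI values with surrogate p ≥ 0.05 are zeroed in the masked matrix. Note
that shift surrogates cannot flag coupling in perfectly periodic toy
signals (the shifted amplitude remains phase-locked); they are meant for
physiological, aperiodic data.

## Laminar

The inverse CSD uses the delta-source model: planar current disks
(default diameter 500 µm, homogeneous relative conductivity) at the
electrode depths; the forward matrix maps disk densities to potentials and
is inverted on the shank-average-referenced, event-triggered mean LFP.
Sinks are negative. The model assumes current flow along the depth axis;
oblique probe insertion violates this on real data, so depth localization
there is approximate — the synthetic checks (forward-model inversion,
zero CSD for curvature-free profiles) validate the estimator, not the
anatomical assumption. ICA depth loadings come from FastICA on
concatenated event windows; the leading component maximizes event-locked
(trial-averaged) source variance weighted by its mixing power, and the
superficial-vs-deep comparison is a two-sided rank-sum on the loadings
(sign-flip invariant).

## Spike-train statistics

PETHs align to ripple onset, use only events ≥ 500 ms from their
neighbours, and z-score against bins ≥ 100 ms pre-onset. Significance is
convolution-based: the per-bin expected count is a Gaussian-weighted
(SD 10 ms) average of the PETH *excluding* the test window (0–100 ms),
blended toward the non-test mean where the kernel has no support; observed
counts are compared against two-sided Poisson bands at a global α = 0.01,
Bonferroni-corrected over tested bins. Measured null flag rate ≈ 0.6–1 %;
a planted 3× / 30 ms gain at 200 events is detected in > 95 % of units.

The standardized cross-covariance bins spike-pair lags (default 10 ms,
±100 ms) with both spikes inside the restriction set; with T the restricted
duration and R₁, R₂ the within-restriction rates,
CCE = CCH/(b·T) − R₁R₂ and the standardized curve CCE·√(b·T/(R₁R₂)) is
unit-normal per bin under independence (verified: mean ≈ 0, SD ≈ 1 over
pooled null pairs at T = 600 s). The curve is antisymmetric under swapping
the trains with lag negation. ISI-violation QC uses a 2 ms refractory
definition (configurable).

## Ripple typing

Rate vectors count spikes in [onset, onset + 100 ms) per non-fast-spiking
unit, z-scored per unit across ripples (min–max available in config);
zero-variance units become zero columns rather than being dropped.
K-means uses k-means++ seeding with a fixed seed (deterministic and
standard) and k = 10 by default.
The similarity matrix is the label-sorted Pearson correlation of rows and
is invariant to per-unit affine rescaling by construction.

The ANCOVA is OLS with label dummies plus the (centred) CA1 population-rate
covariate, and a partial F-test on the label block — verified against
statsmodels' `anova_lm` to 1e-8 and calibrated at α = 0.01 on simulated
Poisson counts. A unit discriminates ripple type if any post-onset 10 ms
bin has label p < 0.01; a label-shuffle null of the maximal F is available
as the guard. The covariate window matches the tested bin for per-bin
tests and the 100 ms vector window at the vector level. LFP discrimination
z-scores wavelet amplitudes per band over each event's ±500 ms window,
runs the same ANCOVA per (band, lag), combines sessions by Fisher's method
(−2Σ log pᵢ ~ χ²(2n); exact for the closed-form uniform case) and masks at
p < 0.0004.

t-SNE embeds CA1 and gRSC vectors separately (perplexity 30, random
Gaussian initialization, fixed seed). The density test bins the embedding
(1 AU), smooths with a 2-D Gaussian (σ = 4 AU), normalizes by the label's
ripple count, and flags bins whose density exceeds the (1 − α) quantile of
1000 label permutations (p computed with the +1 correction). Labels with
fewer than 5 ripples are excluded with a warning. The density test is
exactly invariant to point order given an embedding; the embedding itself
is not float-stable under row permutation, which is why the invariance is
stated at the density-test level. Under label randomization the flagged
fraction fluctuates around the nominal 1 % (bins are spatially correlated
by the smoothing kernel, so single randomizations are lumpy; calibration
statements average several).

## State index and segmentation

The SI is the moving-window (0.5 s) fraction of nonzero 1 ms population
count bins, stepped at the bin width; it is bounded in [0, 1] and monotone
under superposition of additional spikes. EMG-from-LFP band-passes all
channels at 300–600 Hz and averages pairwise correlations over 0.5 s
windows (step 0.25 s). Segmentation cuts both the SI and EMG distributions
at the deepest interior minimum between their two largest smoothed-histogram
modes, falling back to fixed cutoffs with a warning when unimodal; low SI
is synchronized, and desynchronized time splits by the EMG cutoff;
intervals < 2 s are absorbed into their predecessor.

## Analysis sizes

The shipped drivers and checks use desk-scale problem sizes chosen to make
every statistic well-estimated: 600 s sessions (≈ 300 ripples at 0.5 Hz,
≈ 1200 packets), 1000 null units for PETH calibration, 50 pooled pairs
(1050 lag bins) for the cross-covariance null, 100 × 30 s white-noise runs
(200 surrogates each) for PAC calibration, 10–20 seeds for clustering
recovery, 400–1000 simulated responses for ANCOVA calibration/power, and
1000 permutations for the density test. Real sessions (≈ 1 h, 256
channels) simply scale these linearly.

## Known limitations

- The EMG proxy and state segmentation assume the 300–600 Hz band is
  dominated by shared muscular volume conduction; dense local spiking can
  leak into this band.
- The SI contrast requires a pooled population rate high enough to occupy
  1 ms bins in the desynchronized state (hundreds of Hz); sparse sorted
  populations would need multiunit augmentation.
- Shift-surrogate PAC significance is blind to strictly periodic coupling
  and assumes the session is long relative to the slowest phase cycle.
- The delta-source CSD treats conductivity as homogeneous and vertical.
- k = 10 is taken as given for ripple clustering; no model-selection
  criterion is applied beyond an optional silhouette diagnostic.
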