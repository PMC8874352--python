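# Methods

This note documents the generative model, the analysis chain, the default
parameters with their rationale, and the numerical choices that affect
results.

## 1. Stimulus protocol

Trials are five-tone sequences at a 750-ms SOA (sequence duration
3750 ms). The default session has 240 sequences (900 s): 60 contain one
target tone at position 2, 3, or 4 (20 each) and a deviant at position 5;
the remaining 180 end in a deviant with no target. Tone roles therefore
occur with global probabilities 75% (standard), 20% (deviant), 5%
(target). Target-containing sequences are separated by at least two
target-free sequences; feasible placements are sampled uniformly through
the standard bijection between spaced and unconstrained combinations
(choose k indices from n − (g−1)(k−1) without replacement, then add
g·rank offsets, g = 3 here), so every admissible layout is equally likely
and generation is exact rather than rejection-based.

With a uniform prior f = (1/3, 1/3, 1/3) over target positions, the
hazard h(k) = f(k)/(1 − F(k−1)) is (1/3, 1/2, 1): certainty by position 4
given no target yet. This monotone hazard is the experimental lever for
temporal prediction.

Derived rates: tone rate 1/0.75 s = 1.333 Hz, first harmonic 2.667 Hz,
sequence rate 0.267 Hz. On the 8192-point FFT grid at 500 Hz (bin width
0.061 Hz) the bin nearest the tone rate is bin 22 at 1.34 Hz.

## 2. Synthetic EOG generator

Blink times follow a renewal process with thinning. Candidate intervals
are uniform on [3, 5] s (control-like preset; 3.8–6.2 s for the PD-like
preset), matching typical spontaneous blink rates. A candidate at time t
is accepted with probability g(t):

- a **cyclic gain** exp(κ·c·(cos(φ(t) − φ₀) − 1)) with phase φ computed on
  the 750-ms tone cycle, preferred phase φ₀ at 375 ms (mid-interval),
  concentration c = 4, and strength κ (0.8 control-like, 0.4 PD-like) —
  a von-Mises-shaped gain producing entrainment at the tone rate;
- a **suppression gain** exp(β·(position − 2)) applied inside the 300-ms
  windows before the three potential target onsets (750, 1500, 2250 ms
  into the sequence), with β = −0.8 by default, so inhibition deepens
  with position exactly as a hazard-tracking observer would show. Setting
  β = 0 removes the effect (used for null calibration).

A 400-ms refractory period suppresses implausibly close blinks (blink
catalogs in practice show a minimum inter-blink interval near 0.42 s).

Waveforms: a blink is a 90-ms linear up-stroke and a ~200-ms exponential
down-stroke, smoothed with a ~16-ms Hanning kernel; amplitude 100 µV with
15% lognormal-free jitter. It is projected onto channels with gains
+1.0 (vertical upper), −0.8 (vertical lower), and 0.3–0.45 (frontal
sites). Saccades are rendered on the lateral channels as a sharp linear
rise followed by a slow 400-ms exponential settle and appear as Poisson
events. Additive white noise has SD 5 µV by default (≈5% of blink
amplitude). The generator emulates timing structure and the gross
waveform stereotypy of blinks; it does not emulate EEG background
spectra, slow drift, electrode artifacts, or eyelid flutter.

## 3. Blink detection

The detector operates per channel: zero-phase 4th-order Butterworth
band-pass 1–20 Hz (SOS form), z-scoring, candidate runs above
mean + 1.5 SD lasting ≥50 ms with <50-ms gaps merged. For each candidate
the peak and flanking zero crossings (searched up to 1 s) delimit the
blink; lines are fit to the inner 80% (by amplitude span) of the up- and
down-strokes. Quality tiers use the worse of the two R² values
(good/better/best at 0.90/0.95/0.98). Stereotypy filters:

- **BAR** (blink-amplitude ratio, in-blink mean over surrounding positive
  mean) within [3, 20];
- **pAVR** (peak amplitude over maximum up-stroke velocity, scaled by
  0.15) ≥ 3 — blinks have curved ~50–60-ms rises (amplitude/velocity ≈
  24–30 samples) while saccadic rises are sharp (≤17), so this separates
  the two event families without any trained model;
- a robust amplitude gate: within 5 robust SD (1.48 × MAD) of the
  best-tier median (2 SD when only lower tiers exist).

Both signal polarities are tried (the lower vertical channel inverts
blinks) and the orientation keeping more used blinks wins. Channels are
ranked by used-blink count with a fixed priority order for ties; a
channel with fewer than 20 used blinks is marked unstable. On a 15-minute
default-noise synthetic recording the detector recovers ≥95% of
ground-truth blinks within ±20 ms with ≤5% false positives (measured:
99.1% recovery, 0 false positives).

## 4. Entrainment spectra

Blink peak times from the 180 target-free sequences are reduced to an
impulse train. Two reductions are provided:

- `concatenate()` abuts the 3500-ms epochs back to back;
- `timeline_vector()` keeps each impulse at its absolute session time and
  zeros everything else.

The 3500-ms analysis window is 4⅔ tone cycles, so abutting epochs
advances the tone phase by ⅓ cycle per epoch and cancels phase-locked
power at 1.34 Hz; the timeline vector preserves phase and is what the
pipeline uses. Power is |rfft|/N averaged over consecutive 8192-sample
windows. Probe bins are the bins nearest 0.267, 1.34, and 2.67 Hz;
reference power is the median of the ±10 neighboring bins excluding the
probe's immediate neighbors. Peak frequency is the maximal-power bin
restricted to (0, 3] Hz: an impulse comb has non-decaying harmonics, and
harmonics that align exactly with FFT bins (e.g., 129.3 Hz) would
otherwise win the global argmax, so the peak search is confined to the
band containing the rates of interest. Group inference uses Wilcoxon
signed-rank (probe vs. reference within group) and one-sided rank-sum
between groups; effect sizes are reported as r = Z/n and r = Z/(n₁+n₂),
with the conventional Z/√n variant behind a flag.

## 5. Blink histograms and Gaussian fits

Latencies in [0, 3500) ms are binned into 175 half-open 20-ms bins and
normalized to probabilities ("pristine"), then smoothed with a 5-bin
moving median whose window shrinks at the edges (no padding bias). Group
curves are pointwise medians across participants. A sum of five Gaussians
is fit by Nelder–Mead (means initialized at the inter-tone midpoints 375,
1125, 1875, 2625, 3375 ms; σ = 20 ms; amplitudes from the curve; xatol
1e-10, fatol 1e-16, adaptive simplex), minimizing mean absolute
residual. A noiseless 5-Gaussian curve is recovered with mean position
error <5 ms and residual <1e-8 (measured residual ≈ 2e-15).

Group curves are compared with the χ² histogram distance
½·Σ (xᵢ−yᵢ)²/(xᵢ+yᵢ) (0/0 terms contribute 0) and a label-permutation
bootstrap: group labels are reshuffled n times, the distance between the
permuted group medians forms the null, and
p = (1 + #{null ≥ observed})/(n + 1). Per-interval tests compare the two
groups' pristine masses at the bins containing the first group's fitted
peaks, rank-sum with Benjamini–Hochberg FDR correction.

## 6. Hazard-rate slopes and cluster inference

Per participant, blink frequency (counts over total blinks) is tabulated
in thirty 20-ms bins spanning ±300 ms around each potential target onset
(bin edge at the onset). For each time bin the frequency at positions
2/3/4 is regressed on centered codes (−1, 0, 1) with a Tukey-bisquare
IRLS slope (c = 4.685, scale 1.48 × MAD, OLS fallback when the scale
collapses; an all-equal triple returns exactly 0). A negative slope means
inhibition deepening with hazard.

Group inference: per-bin one-sample t statistics (moment form shared with
the permutation null so the identity sign pattern reproduces the observed
t exactly), one-sided threshold t(0.05, n−1), contiguous sub-threshold
bins form clusters scored by mass (summed t; a t-max variant is
available). The null flips the sign of each participant's entire slope
vector, recording the most negative cluster mass per permutation; the
flips are vectorized using the sign-invariance of per-bin second moments.
Enumeration is exhaustive when 2ⁿ ≤ n_perm; otherwise 2000 random flips.
p = (1 + #{null ≤ observed})/(n_eff + 1). Calibration: over 200 null
cohorts (β = 0, n = 15) the family-wise rejection count lies within the
binomial 95% CI of α = 0.05, and at β = −1 a significant pre-stimulus
cluster appears in ≥90% of cohorts; at n = 6 results agree exactly with
brute-force enumeration of all 64 sign patterns.

## 7. Saccade scoring

Candidates on the bipolar horizontal derivation are velocity-magnitude
peaks above median + 4 robust SD of the smoothed derivative. Features
(peak velocity, displacement amplitude, duration from the same-sign
velocity run above a 10% floor) are z-scored and modeled with a
2-component full-covariance Gaussian mixture (EM, 5 restarts, fixed
seed) trained on a 50–200-s stretch; the higher-velocity component is the
saccade class and events receive its posterior probability. Events inside
detected blink intervals (±150 ms) are excluded. The model is flagged
degenerate when the standardized velocity means separate by <0.5. Group
comparison uses rank-sum tests on per-participant variances of event
attributes. This is a compact probabilistic detector, not
eye-tracking-grade metrology.

## 8. Cohort pipeline

`run_pipeline` drives everything from one master seed (participant seeds
come from `SeedSequence.spawn`, reduced mod 2³¹). With `render=False`
blink catalogs are built directly from sampled ground-truth times (fast
path for calibration studies: a 30-participant cohort takes ~2 s); with
`render=True` full waveforms are synthesized and pass through the
detector. Outliers (blink count >3 × IQR above the group's upper
quartile) are removed with their matched partner. Cohort statistics:
one-sided rank-sum on counts and median IBIs, a Kolmogorov–Smirnov
normality screen motivating the non-parametric tests, Tukey-bisquare
robust regression of paired counts, and Spearman correlation with age.
All JSON is written with sorted keys and hashed into a manifest; two runs
from the same seed are byte-identical.

## Problem sizes used in validation

- Detector recovery: one 15-minute, 6-channel, 500-Hz recording.
- Cluster calibration: 200 null cohorts and 50 effect cohorts of 15
  participants × 240 sequences each, 1000 permutations per test.
- Bootstrap calibration: 200 null replicates of 16 curves, 200
  randomizations each.
- Determinism: the default 30-participant pipeline run twice.

## Limitations

- The generator's suppression is a hard windowed exponential gain, not a
  mechanistic oculomotor model; β is a phenomenological knob.
- Effect sizes r = Z/n and Z/(n₁+n₂) are reported for comparability with
  common practice in this literature despite Z/√n being the conventional
  definition; both are labeled and the conventional form is available.
- The spectral reference (median of neighboring bins) assumes locally
  flat background power; it is biased near very sharp spectral features.
- Saccade durations are estimated from velocity runs and are accurate to
  ~5 ms on clean synthetic data only.
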