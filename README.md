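# blinkhazard

Blink-timing analysis for auditory temporal-prediction experiments:
synthetic EOG generation, waveform blink detection, entrainment spectra of
blink point processes, Gaussian-structured blink histograms, and
hazard-rate analysis of pre-stimulus oculomotor inhibition, with a
two-cohort comparison pipeline (control-like vs. Parkinsonian-like blink
generators).

## Scientific problem

Spontaneous eye blinks are not uniformly distributed in time when people
listen to a predictable stimulus stream. With tones presented at a fixed
750-ms stimulus onset asynchrony (SOA) in repeating five-tone sequences,
blinks entrain to the stimulus rhythm and are selectively withheld just
before moments when a behaviorally relevant target could occur. If a rare
target can appear at sequence positions 2, 3, or 4 with equal probability,
the conditional probability that it occurs at position k given that it has
not occurred yet — the hazard rate

```
h(k) = f(k) / (1 − F(k−1))   →   h = (1/3, 1/2, 1)
```

— rises across the sequence, and pre-stimulus blink inhibition deepens
with it. The package quantifies three signatures of this temporal
prediction in the blink point process:

1. **Entrainment**: the FFT of the blink impulse train shows power at the
   tone rate (1.33 Hz; nearest 8192-point bin at 500 Hz is 1.34 Hz), its
   first harmonic (2.67 Hz), and the sequence rate (0.267 Hz).
2. **Within-sequence structure**: blink histograms over the 3.5-s analysis
   window of a sequence are well described by a sum of five Gaussians, one
   per inter-tone interval; group histograms are compared with a χ²
   distance and a label-permutation bootstrap.
3. **Hazard-rate inhibition**: blink frequency in the 300 ms before each
   potential target onset, regressed on position with a Tukey-bisquare
   robust slope per 20-ms bin, yields negative slopes whose group-level
   significance is assessed with a one-sample sign-flipping cluster
   permutation test.

Because the blink generator in Parkinson's disease is slower and less
entrained, the package ships two synthetic presets ("HC-like" and
"PD-like") that differ in baseline blink interval and cyclic-gain
concentration, allowing end-to-end power and calibration studies without
patient data.

## Worked example

```python
import numpy as np
from blinkhazard import protocol, synth_eog, blink_detect, spectral, hazard_slopes

# 240 five-tone sequences at 750-ms SOA; 60 contain a target at position 2-4
prot = protocol.generate_protocol(n_sequences=240, n_target_sequences=60, seed=0)
rep = protocol.validate_protocol(prot)
print(rep.role_counts)                      # {'standard': 900, 'deviant': 240, 'target': 60}
print(protocol.hazard((1/3, 1/3, 1/3)).h)   # [0.333 0.5   1.   ]

# synthesize a 15-minute EOG recording with entrained, target-inhibited blinks
model = synth_eog.TimingModel(seed=41)
truth = synth_eog.sample_blink_times(model, prot)
rec, _ = synth_eog.render_recording(truth, duration_ms=prot.duration_ms,
                                    rng=np.random.default_rng(42))

# detect blinks from the waveform and check recovery against ground truth
catalog = blink_detect.select_best_signal(rec, participant_id="demo")
det = catalog.peak_times_ms()
recovery = np.mean([np.min(np.abs(det - t)) <= 20 for t in truth])
print(len(truth), catalog.n_used, round(recovery, 3))   # 226 224 0.991
print(round(np.median(catalog.inter_blink_intervals_ms()) / 1000, 2))  # 3.86 s

# spectral entrainment of the blink point process
ep = spectral.extract_epochs(catalog, prot)
vec = spectral.timeline_vector(ep, duration_ms=prot.duration_ms)
sp = spectral.fft_power(vec)
print(round(sp.peak_frequency(), 3))        # 1.343 Hz
print(f"{sp.peak_power[1.34]:.3e} vs reference {sp.reference_power[1.34]:.3e}")
# 3.328e-04 vs reference 1.821e-04

# pre-stimulus inhibition deepens with the hazard of the upcoming position
peri = hazard_slopes.build_peristim(ep)
print(peri.freq[:, :15].sum(axis=1).round(4))   # [0.0465 0.0116 0.0116]
```

Running the full two-cohort pipeline (15 synthetic participants per group,
seeded end to end):

```python
from blinkhazard import cohort_report
res = cohort_report.run_pipeline({"seed": 0})
```

prints-worthy results from that exact call:

- blink-count medians 229 (HC-like) vs 178 (PD-like), one-sided rank-sum
  Z = 4.67, p = 1.5e-06;
- χ² distance between group median histograms 0.059, permutation
  p = 0.001 at 1000 randomizations;
- HC-like pre-stimulus cluster from −300 to −180 ms, mass −19.6,
  p = 0.0005; PD-like cluster −300 to −200 ms, mass −17.8, p = 0.001;
- fitted Gaussian means 387, 1131, 1874, 2640, 3387 ms — one per
  inter-tone interval midpoint.

The same pipeline is exposed on the command line:

```bash
blinkhazard run config.yaml      # YAML keys mirror cohort_report.DEFAULT_CONFIG
```

## Layout

- `src/blinkhazard/protocol.py` — stimulus stream generation/validation, hazard table
- `src/blinkhazard/synth_eog.py` — renewal-with-thinning blink sampler, waveform renderer, cohort generator
- `src/blinkhazard/blink_detect.py` — bandpass + landmark + stereotypy blink detector
- `src/blinkhazard/spectral.py` — epoching, point-process vectors, FFT power, entrainment statistics
- `src/blinkhazard/distfit.py` — histograms, 5-Gaussian fits, χ² distance, bootstrap and per-interval tests
- `src/blinkhazard/hazard_slopes.py` — peri-stimulus matrices, robust slopes, cluster permutation
- `src/blinkhazard/saccade_em.py` — EM-based probabilistic saccade scoring on horizontal EOG
- `src/blinkhazard/cohort_report.py` — outlier exclusion, cohort statistics, end-to-end pipeline
- `docs/methods.md` — methods note with parameter rationale and numerical choices
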