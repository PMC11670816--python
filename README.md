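# coilcomp

Quantitative machinery for within-subject comparisons of two TMS coils —
for example a quiet double-containment coil against a conventional
figure-8 coil — covering stimulation strength, perceived loudness, and
EEG-evoked responses. The package is aimed at TMS-EEG and psychophysics
researchers who want the full analysis chain as tested, reusable code:
every stage runs against simulated observers and synthetic EEG, so no
recorded data are needed to exercise or validate it.

## What it implements

**Adaptive motor thresholding** (`coilcomp.threshold`). Maximum-likelihood
sequential estimation (ML-PEST style) of the resting motor threshold: a
uniform prior over an integer %MSO grid, probit trial likelihood
P(MEP ≥ 50 μV | θ) = Φ((a − θ)/s), stimulation at the running ML estimate,
ten confirmation pulses after convergence, and a single restart if the
estimate moves by more than 2 %MSO during confirmation. Trials with
pre-pulse EMG activity ("facilitated") are logged but never enter the
likelihood.

**2AFC loudness matching** (`coilcomp.titration`). A transformed staircase
matches the test coil's amplitude to a fixed reference-coil loudness:
pairs of pulses, "which was louder?", amplitude lowered after "test
louder" and raised otherwise, step halved at each choice reversal
(16 → 8 → 4 → … %RMT, floored at 1). The run stops at the 11th reversal;
the match point is the mean of the last six reversal amplitudes. Matched
amplitudes are normalized as ln(a / mean RMT) for group statistics.

**ERP pipeline** (`coilcomp.erp`). Pulse-artifact excision (−8…15 ms,
cubic), joint-probability trial rejection (local/global 3.3 SD),
variance/flatline/correlation bad-channel detection, zero-phase 57–63 Hz
band-stop and 1–100 Hz band-pass filtering, spherical-spline
interpolation of missing electrodes, average reference, −400…400 ms
trimming with −400…−10 ms baseline, global mean field amplitude
GMFA(t) = √(Σᵢ(vᵢ(t) − v̄(t))²/N), windowed peak extraction, and
ROI selection by a ≥2 μV grand-average magnitude criterion.

**Cluster permutation statistics** (`coilcomp.clusterstats`). Paired
t-maps over channels × time, cluster formation under spatiotemporal
adjacency, cluster mass Σt, and a max-mass Monte-Carlo null from
per-subject condition swaps (sign flips), 256 permutations by default
with exact exhaustive enumeration when 2ⁿ is within reach.

**Group statistics** (`coilcomp.groupstats`). Repeated-measures ANOVA
(any fully crossed within-subject design), paired t on subject medians,
paired Cohen's d, and leave-p-out robustness: rerun the ANOVA on every
subject subset of sizes 3…n−1 and report the worst-case p per size.

**Synthetic data** (`coilcomp.simulate`). Probit observers for MEPs and
2AFC loudness, plus an EEG generator: Gaussian-windowed evoked
components at 32/56/100/186/275 ms with spatially smooth topographies,
spatially correlated 1/f background, 60 Hz line noise, a TMS artifact,
and injectable bad channels/trials with recoverable ground truth.

**I/O** (`coilcomp.io`). BrainVision triplets (.vhdr/.vmrk/.eeg,
multiplexed IEEE float32 written, INT_16 with resolutions also read),
montage tables, CSV results, and JSON run reports with config hashes.

## Worked example

```python
import numpy as np
from coilcomp import (LoudnessObserver, MotorObserver, TitrationConfig,
                      estimate_rmt, run_titration, simulate_mep_trial,
                      percent_reduction)

# Match the loud coil to a quiet-coil reference at 100 %RMT:
obs = LoudnessObserver(pse=34.4, sigma=2.0)       # true equal-loudness point
res = run_titration(obs, TitrationConfig(reference_amplitude=100.0), seed=3)
print("match %RMT:", round(res.match, 2), "| pairs:", res.n_pairs,
      "| reversals:", len(res.reversal_amplitudes))

# Adaptive motor thresholding against a probit observer:
motor = MotorObserver(threshold=52.0, spread=2.0)
rng = np.random.default_rng(5)
rmt = estimate_rmt(lambda a: simulate_mep_trial(motor, a, rng), start=65.0)
print("RMT %MSO:", rmt.rmt, "| pulses:", rmt.n_pulses, "| restarted:", rmt.restarted)

# Amplitude reduction at matched loudness across six condition means:
red = percent_reduction([29.7, 34.4, 42.8, 32.5, 44.3, 55.8],
                        [80, 100, 120, 80, 100, 120])
print("amplitude reduction at matched loudness: %.1f %%" % red)
```

Output:

```
match %RMT: 35.33 | pairs: 21 | reversals: 11
RMT %MSO: 52.0 | pulses: 23 | restarted: False
amplitude reduction at matched loudness: 60.2 %
```

The staircase landed within one terminal step of the observer's true
34.4 %RMT equal-loudness point after 21 pulse pairs; the threshold
estimator recovered the observer's 52 %MSO threshold in 23 pulses with a
stable confirmation phase; and the six condition-mean matched amplitudes
correspond to a 60.2 % amplitude reduction at matched loudness.

A command-line surface wraps the same functions:
`coilcomp simulate | rmt | titrate | erp | cluster | groupstats | reproduce`
(see `coilcomp --help`).

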