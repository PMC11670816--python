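# Methods

This note documents the models behind `coilcomp`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Observer models

Both psychophysical observers use probit (cumulative-Gaussian)
psychometric functions — the standard two-parameter, symmetric choice in
psychophysics.

**Motor observer.** A trial at amplitude `a` %MSO crosses the 50 μV MEP
criterion with probability Φ((a − θ)/σ), where θ is the resting motor
threshold (the 50 % point) and σ the psychometric spread in %MSO.
Per-subject psychometric slopes are not identifiable from group
summaries, so the default σ = 2 %MSO is a convention in the typical
1–5 %MSO range; estimator consistency is tested across that range.
Suprathreshold MEP amplitudes are lognormal peak-to-peak values only —
no EMG waveform is simulated. A facilitation flag (pre-pulse EMG
activity) is drawn independently of amplitude at a configurable rate.

**Loudness observer.** In a two-interval pair (reference coil at fixed
%RMT, test coil variable) the observer reports "test louder" with
probability (1 − λ)·Φ((a − pse)/σ) + λ/2. Loudness is modelled directly
on the stimulator-amplitude axis: the large sound-pressure gap between a
quiet double-containment coil and a conventional coil (~35 dB(Z)) is
absorbed into the point of subjective equality, which sits far below the
reference amplitude (e.g. pse ≈ 34 %RMT against a 100 %RMT reference).
Only the matched amplitude is observable in practice, so an explicit
dB-SPL-to-loudness transform would add parameters with nothing to
constrain them.

## Adaptive threshold estimation

Maximum-likelihood sequential estimation on an integer grid 1…100 %MSO
(stimulator outputs are integer-valued) with a flat prior and fixed
assumed slope (default 2 %MSO, configurable). Each non-facilitated trial
adds its probit log-likelihood to every grid candidate; the next
stimulus is the current ML estimate, ties breaking toward the lower
integer; the configured start amplitude (default 65 %MSO, the hotspot-
search level) is used before the first valid trial. Facilitated trials
append to the history only, so injecting them anywhere never changes
the estimate.

Initial convergence is declared when the integer estimate has been
stable over 3 consecutive valid pulses (minimum 10), where "stable"
allows the estimate to dwell on a single value; afterwards ten
confirmation pulses are delivered while the estimate continues to
update. If the confirmation estimates span more than 2 %MSO, the whole
cycle restarts once from the current estimate; a second instability is
accepted with the span recorded. A 200-pulse budget bounds the session;
exhausting it returns an explicit non-converged result rather than a
number.

With a flat prior, the first all-positive (or all-negative) run sends
the ML estimate to the grid edge — the estimator briefly probes very low
amplitudes before bracketing the threshold. This is the known behavior
of flat-prior ML-PEST and resolves within a few pulses.

## Loudness titration

The staircase starts at the reference amplitude with a geometric step
rule: 16 %RMT, halved at every reversal, floored at 1 %RMT. The exact
step rule used with this protocol family is not standardized, so the
rule is a pluggable strategy (`GeometricStepRule` is the default);
the default reproduces run lengths of roughly 20–24 pairs to the 11th
reversal, consistent with equal-loudness titrations of this design.
Amplitudes are tracked continuously in %RMT; quantization to integer
%MSO belongs at the delivery boundary, not in the staircase state.
Presentation order is counterbalanced within every block of ten pairs
(five reference-first, five test-first, seeded shuffle) and recorded as
metadata; the 400 ms between the two pulses of a pair and side swapping
carry no computation and are likewise metadata only.

Termination is exactly at the 11th reversal; the match is the mean of
the last six reversal amplitudes. All pairs are counted in `n_pairs`,
including those before the first reversal. For group analyses, matched
amplitudes are divided by the condition's mean RMT and log-transformed
(`ln(a/RMT)`), which puts both coils on a common relative scale and
reduces heteroscedasticity; `percent_reduction` summarizes condition
means as 100·(1 − mean(matched/reference)).

## Synthetic EEG

The generator emulates epoched 63-channel, 1 kHz recordings spanning
±1.3 s around the pulse:

- **Montage:** Fibonacci lattice on the spherical cap z ≥ −0.15 —
  quasi-uniform, deterministic, label-stable. Real cap geometry
  (10–10 names, fiducials) is not modelled.
- **Components:** Gaussian-in-time deflections with Gaussian spatial
  profiles in great-circle distance from a center electrode. Defaults
  place five components at 32, 56, 100, 186 and 275 ms (the P30/P60/
  N100/P180/N280 family seen in combined TMS/auditory stimulation) with
  amplitudes 4, 3.5, −8, 7, −4 μV and temporal SDs 6, 8, 15, 25, 22 ms —
  grand-average-like morphology. The late negative component's width is
  kept at 22 ms because a much flatter bump has no well-defined peak
  latency at realistic noise levels. Per-condition gains scale
  components linearly.
- **Noise:** 1/f-spectrum Gaussian background, spatially smoothed across
  the cap (Gaussian kernel, SD 0.6 rad) because volume conduction makes
  real background activity strongly correlated between neighboring
  electrodes — spatially white noise would give artifact-rejection
  statistics 60-odd independent chances per trial to fire, which real
  data do not. Default per-channel RMS 3 μV. Line noise at 60 Hz with
  per-trial random phase, RMS 1 μV.
- **Artifact and contamination:** a decaying high-amplitude oscillation
  in −8…15 ms; an exact count `round(fraction × n_trials)` of bad trials
  carrying large low-frequency drifts; injected bad channels replaced by
  uncorrelated high-variance noise. Ground truth is recorded in
  `Epochs.info` so rejection stages can be scored.
- **Trial count:** default 200, the number of stimuli delivered per
  condition in this protocol family (of which ~85–95 % survive
  rejection here).

Not emulated: biophysical forward models, real electrode geometry,
muscle/ocular artifacts, inter-subject variability of component
latencies, EMG waveforms, audio. Passing round-trip tests therefore
shows the pipeline recovers what the generator encodes — smooth evoked
structure in realistic noise — not that it is robust to every failure
mode of recorded EEG.

A single seed fans out to per-stage substreams (`SeedSequence.spawn`-
style keyed sequences), so stages can be rerun independently and
everything is bit-reproducible.

## ERP pipeline

Order: artifact excision → bad-channel detection → joint-probability
trial rejection → filtering → spherical interpolation → average
reference → trim/baseline, mirroring standard TMS-EEG practice. Notable
choices:

- **Excision** replaces −8…15 ms with a per-channel, per-trial cubic
  least-squares fit anchored on 5 samples each side; cubic reproduces
  linear trends exactly and cannot reintroduce the artifact.
- **Trial rejection** estimates each channel's value distribution by a
  100-bin histogram; a trial's statistic per channel is its mean log
  density. Trials beyond 3.3 SD on any channel (local) or on the
  channel-sum (global) are removed, and the procedure is iterated once
  on the survivors. Zero-variance distributions reject nothing.
- **Channel detection** replaces toolbox automated cleaning (and the
  SOUND noise-suppression algorithm) with a defined rule: robust-z of
  log total variance > 5, flatline, or maximal inter-channel correlation
  < 0.4. The substitution is written into the provenance log.
- **Filters** are 4th-order zero-phase Butterworth (band-stop 57–63 Hz,
  band-pass 1–100 Hz); zero-phase filtering preserves peak latencies.
- **Spherical-spline interpolation** uses the surface-spline kernel with
  stiffness order 4, a 50-term Legendre series, and ridge regularization
  1e−5; the unpenalized constant term makes spatially uniform fields
  exact.
- **GMFA** is computed after baselining (per the pipeline order); peak
  search windows default to P30 [20,40], N45 [35,55], P60 [50,75],
  N100 [75,130], P180 [130,240], N280 [240,320] ms, anchored to the
  conventional early/mid/late partition at 75/130/240 ms; GMFA windows
  merge the first two component windows into [20,45]/[45,75] since the
  unsigned global field shows one maximum per deflection. Peak = largest
  local extremum of matching polarity in the closed window; ties break
  earlier; windows with no local extremum report absent rather than an
  endpoint.
- **ROI selection** keeps electrodes whose grand-average magnitude is
  ≥ 2 μV at every supplied peak timepoint.

## Cluster statistics

Paired t-maps on subject condition differences; cluster-forming
threshold is the two-sided critical t at α = 0.05 for n−1 degrees of
freedom (the threshold is unstated in this protocol family; it is
configurable). Clusters are connected components over (same channel,
adjacent samples) ∪ (neighboring channels, same sample), per sign;
channel adjacency is great-circle distance ≤ 0.6 rad by default. The
statistic is cluster mass (sum of t); the null is the maximal mass over
per-subject sign flips. With 256 requested permutations and 2ⁿ ≤ 256
subjects' patterns available, enumeration is exhaustive and p-values are
exact proportions (identity included); otherwise Monte-Carlo sampling
with the +1 correction keeps p ≥ 1/(n_perm + 1). One-tailed direction is
a config argument (the scientific hypothesis here — reduced auditory
response — is directional); the analysis window is ±400 ms with
−10…20 ms masked out to suppress the pulse artifact. Degenerate
zero-variance cells map to t = 0 before clustering in permutation mode
(an infinite t would otherwise dominate every null).

## Group statistics

The within-subject ANOVA is fitted by statsmodels' `AnovaRM`
(conventional subject × effect error terms); partial η² is derived as
F·df₁/(F·df₁ + df₂). No sphericity correction is applied by default:
two-level factors need none, and corrected output for the 3-level
intensity factor can be requested when warranted. Balanced, fully
crossed designs are required; replicates within a cell are averaged
before fitting. `leave_p_out_cv` enumerates all C(n, k) subject subsets
for each size and reports the maximum p of the named effect — the
worst-case-over-subsets reading of robustness; degenerate subset fits
are excluded with a warning and recorded. On 2-level single-factor
designs the ANOVA F equals the squared paired t exactly, which is kept
as a cross-check against the independent t-test path.

## Problem sizes

The packaged recovery runs use 100 simulated loudness observers × 2
staircase runs, 500 threshold-estimation sessions, and one 200-trial
63-channel synthetic EEG session; these sizes give Monte-Carlo standard
errors well inside the tolerances they are checked against while
keeping a full rerun under a minute of compute.

## Known limitations

- The staircase's step rule is a declared convention; a protocol using
  asymmetric or non-geometric steps will converge differently (the rule
  is pluggable for that reason).
- The trial-rejection statistic's null distribution is heavier-tailed
  than Gaussian, so the 3.3 SD limit removes somewhat more clean trials
  (~5–15 %) than a Gaussian calibration would suggest; this mirrors the
  behavior of joint-probability rejection on real data.
- Spherical-spline interpolation error grows for electrodes near the
  cap edge, where the field is constrained from one side only.
- The cluster test supports paired designs only; no TFCE, no
  between-subject designs.
- `rm_anova` reports conventional error degrees of freedom; published
  tables in this protocol family occasionally print other df
  conventions for 3-level factors, which should be checked before
  comparing p-values digit for digit.
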