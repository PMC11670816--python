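"""Simulated observers and synthetic TMS-EEG recordings.

Two psychophysical observers are modelled with probit psychometric
functions: a motor observer producing Bernoulli MEP responses around a
resting-motor-threshold, and a loudness observer judging which of two
coil clicks sounded louder in a 2AFC pair. A companion EEG generator
produces epoched multichannel data with Gaussian-windowed evoked
components, 1/f background noise, 60 Hz line noise, a TMS pulse
artifact, and injectable bad channels/trials, so the full analysis
chain can be exercised without recorded data.

Loudness is modelled directly on the stimulator-amplitude axis (%RMT):
the ~35 dB(Z) sound-pressure gap between a conventional figure-8 coil
and a quiet double-containment coil is absorbed into the observer's
point of subjective equality, which sits far below the reference
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .containers import Epochs, Montage

#: Evoked components used by default, as (label, latency ms, temporal sd ms,
#: peak amplitude uV, topography center channel index, spatial sd rad, gain).
#: Latencies follow the five maxima a global-field analysis of combined
#: TMS/auditory stimulation typically shows (P30, P60, N100, P180, N280
#: family); amplitudes are in the range of grand-average scalp ERPs.
DEFAULT_COMPONENTS = (
    ("P30", 32.0, 6.0, 4.0, 0, 0.45, 1.0),
    ("P60", 56.0, 8.0, 3.5, 2, 0.45, 1.0),
    ("N100", 100.0, 15.0, -8.0, 1, 0.55, 1.0),
    ("P180", 186.0, 25.0, 7.0, 1, 0.55, 1.0),
    ("N280", 275.0, 22.0, -4.0, 3, 0.6, 1.0),
)


@dataclass(frozen=True)
class MotorObserver:
    """Probit MEP observer.

    threshold: %MSO at which P(MEP >= 50 uV) = 0.5.
    spread: psychometric slope (probit sigma) in %MSO.
    mep_scale: median suprathreshold MEP peak-to-peak amplitude, uV.
    facilitation_rate: probability that a trial shows pre-pulse EMG
        activity >= 50 uV and must be excluded from analysis.
    """

    threshold: float
    spread: float = 2.0
    mep_scale: float = 500.0
    facilitation_rate: float = 0.0

    def __post_init__(self):
        if not 0 < self.threshold <= 100:
            raise ValueError("threshold must be in (0, 100] %MSO")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if not 0 <= self.facilitation_rate < 1:
            raise ValueError("facilitation_rate must be in [0, 1)")

    def p_response(self, amplitude: float) -> float:
        """P(MEP peak-to-peak >= 50 uV) at the given amplitude (%MSO)."""
        return float(norm.cdf((amplitude - self.threshold) / self.spread))


@dataclass(frozen=True)
class LoudnessObserver:
    """Probit 2AFC loudness observer on the %RMT amplitude axis.

    pse: test-coil amplitude (%RMT) perceived as loud as the reference.
    sigma: decision-noise SD in %RMT-equivalents.
    lapse: probability of a uniformly random response.
    """

    pse: float
    sigma: float = 2.0
    lapse: float = 0.0

    def __post_init__(self):
        if self.pse <= 0:
            raise ValueError("pse must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")

    def p_test_louder(self, test_amplitude: float) -> float:
        p = norm.cdf((test_amplitude - self.pse) / self.sigma)
        return float((1 - self.lapse) * p + self.lapse / 2)


def simulate_mep_trial(observer: MotorObserver, amplitude: float, rng) -> tuple[float, bool]:
    """One simulated single-pulse trial.

    Returns (mep_pp_uV, facilitated). The MEP response crosses the 50 uV
    criterion with probit probability Phi((amplitude - threshold)/spread);
    the facilitation flag is drawn independently of amplitude.
    """
    if not 0 <= amplitude <= 100:
        raise ValueError("amplitude must be in [0, 100] %MSO")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    facilitated = bool(rng.random() < observer.facilitation_rate)
    responded = rng.random() < observer.p_response(amplitude)
    if responded:
        # Lognormal suprathreshold amplitude, always above criterion.
        mep = 50.0 + observer.mep_scale * rng.lognormal(mean=0.0, sigma=0.5)
    else:
        mep = 50.0 * rng.random()
    return float(mep), facilitated


def simulate_2afc(observer: LoudnessObserver, test_amplitude: float, rng) -> str:
    """One 2AFC judgment: returns 'test_louder' or 'reference_louder'."""
    if test_amplitude <= 0:
        raise ValueError("test_amplitude must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = observer.p_test_louder(test_amplitude)
    return "test_louder" if rng.random() < p else "reference_louder"


def generate_montage(n_channels: int = 63) -> Montage:
    """Quasi-uniform electrode layout on a spherical cap.

    Channels are placed on a Fibonacci lattice over the cap z >= -0.15
    (roughly the scalp area covered by a recording cap), vertex first.
    Deterministic; labels are E1..En.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    z_min = -0.15
    golden = (1 + 5**0.5) / 2
    i = np.arange(n_channels)
    # Uniform in z over the cap, golden-angle spiral in azimuth.
    z = 1.0 - (i + 0.5) * (1.0 - z_min) / n_channels
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = tuple(f"E{k + 1}" for k in range(n_channels))
    return Montage(labels, pos)


@dataclass
class EEGSimSpec:
    """Parameters of the synthetic epoched-EEG generator.

    Components are (label, latency ms, temporal sd ms, peak amplitude uV,
    center channel index, spatial sd in radians of great-circle distance,
    per-condition gain). Noise amplitudes are per-channel RMS in uV.
    """

    montage: Montage
    srate: float = 1000.0
    n_trials: int = 200  # stimuli delivered per condition in the protocol
    epoch_span_ms: tuple[float, float] = (-1300.0, 1300.0)
    components: tuple = DEFAULT_COMPONENTS
    noise_1f_amp: float = 3.0
    line_noise_amp: float = 1.0
    line_freq: float = 60.0
    artifact_window_ms: tuple[float, float] = (-8.0, 15.0)
    artifact_amp: float = 0.0
    bad_channel_labels: tuple[str, ...] = ()
    bad_trial_fraction: float = 0.0
    bad_trial_amp: float = 400.0

    def __post_init__(self):
        lo, hi = self.epoch_span_ms
        for comp in self.components:
            lat = comp[1]
            if not lo < lat < hi:
                raise ValueError(f"component latency {lat} ms outside epoch")
            if comp[6] < 0:
                raise ValueError("condition gains must be >= 0")
        if not 0 <= self.bad_trial_fraction <= 0.5:
            raise ValueError("bad_trial_fraction must be in [0, 0.5]")
        for lab in self.bad_channel_labels:
            if lab not in self.montage.labels:
                raise ValueError(f"bad channel {lab!r} not in montage")


def _one_over_f_noise(rng, n_ch, n_samp, n_trials, srate, rms, angles=None,
                      spatial_sd: float = 0.6):
    """Spatially smooth Gaussian noise with ~1/f amplitude spectrum.

    Background EEG is correlated across nearby electrodes through volume
    conduction; channel noise is therefore mixed through a Gaussian
    smoothing kernel in great-circle distance (``spatial_sd`` radians)
    before scaling the result to the requested per-channel RMS.
    """
    white = rng.standard_normal((n_ch, n_samp, n_trials))
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / srate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # power ~ 1/f
    spec = np.fft.rfft(white, axis=1) * shaping[None, :, None]
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    if angles is not None and spatial_sd > 0:
        kernel = np.exp(-0.5 * (angles / spatial_sd) ** 2)
        x = np.einsum("cd,dst->cst", kernel, x)
    std = x.std()
    if std > 0:
        x *= rms / std
    return x


def generate_epochs(spec: EEGSimSpec, condition_gains: dict | None = None, seed=0) -> Epochs:
    """Synthesize epoched EEG per ``spec``.

    ``condition_gains`` maps component labels to multiplicative gains on
    top of the per-component gain in the spec (absent labels keep gain 1).
    Injected bad trials/channels are recorded in ``epochs.info`` as ground
    truth for rejection tests. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    mont = spec.montage
    n_ch = len(mont)
    lo, hi = spec.epoch_span_ms
    dt = 1000.0 / spec.srate
    times = np.arange(lo, hi + dt / 2, dt)
    # force exact 0 on the axis
    times = times - times[np.argmin(np.abs(times))]
    n_samp = times.size
    n_trials = spec.n_trials
    gains = dict(condition_gains or {})

    data = np.zeros((n_ch, n_samp, n_trials))
    angles = np.arccos(mont.cosine_angles())  # (n_ch, n_ch) great-circle distances

    for label, lat, width, amp, center, spatial_sd, base_gain in spec.components:
        gain = base_gain * gains.get(label, 1.0)
        if gain == 0 or amp == 0:
            continue
        temporal = np.exp(-0.5 * ((times - lat) / width) ** 2)
        topo = np.exp(-0.5 * (angles[:, center] / spatial_sd) ** 2)
        data += (amp * gain) * topo[:, None, None] * temporal[None, :, None]

    if spec.noise_1f_amp > 0:
        data += _one_over_f_noise(rng, n_ch, n_samp, n_trials, spec.srate,
                                  spec.noise_1f_amp, angles=angles)
    if spec.line_noise_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_trials)
        t_s = times / 1000.0
        line = np.sin(2 * np.pi * spec.line_freq * t_s[None, :] + phases[:, None]).T
        data += spec.line_noise_amp * np.sqrt(2) * line[None, :, :]

    if spec.artifact_amp > 0:
        a_lo, a_hi = spec.artifact_window_ms
        in_win = (times >= a_lo) & (times <= a_hi)
        tw = times[in_win]
        # decaying oscillation starting at the pulse, common topography
        env = np.exp(-np.clip(tw, 0, None) / 5.0)
        art = spec.artifact_amp * env * np.cos(2 * np.pi * 0.2 * tw)
        topo = 0.5 + 0.5 * rng.random(n_ch)
        data[:, in_win, :] += topo[:, None, None] * art[None, :, None]

    n_bad_trials = int(round(spec.bad_trial_fraction * n_trials))
    bad_trial_idx = rng.choice(n_trials, size=n_bad_trials, replace=False) if n_bad_trials else np.array([], dtype=int)
    for ti in bad_trial_idx:
        # large low-frequency contamination across most channels
        drift_f = rng.uniform(0.5, 2.0)
        drift = spec.bad_trial_amp * np.sin(2 * np.pi * drift_f * times / 1000.0 + rng.uniform(0, 2 * np.pi))
        ch_w = rng.uniform(0.5, 1.5, size=n_ch)
        data[:, :, ti] += ch_w[:, None] * drift[None, :]

    bad_ch_idx = [mont.index(l) for l in spec.bad_channel_labels]
    for ci in bad_ch_idx:
        # uncorrelated high-amplitude noise replaces physiological signal
        data[ci] = 50.0 * spec.noise_1f_amp * rng.standard_normal((n_samp, n_trials)) if spec.noise_1f_amp > 0 else 100.0 * rng.standard_normal((n_samp, n_trials))

    ep = Epochs(
        data=data,
        srate=spec.srate,
        times=times,
        ch_names=tuple(mont.labels),
        montage=mont,
        info={
            "true_bad_trials": sorted(int(i) for i in bad_trial_idx),
            "true_bad_channels": list(spec.bad_channel_labels),
            "seed": seed,
        },
    )
    ep.log(
        "generate_epochs",
        n_trials=n_trials,
        n_channels=n_ch,
        srate=spec.srate,
        seed=seed,
        condition_gains=gains,
    )
    return ep
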