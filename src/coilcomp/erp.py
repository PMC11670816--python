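"""Epoch-level EEG preprocessing and ERP summarization.

The pipeline mirrors a standard TMS-EEG preprocessing chain: excision
and interpolation of the pulse artifact, bad-channel detection,
joint-probability trial rejection, band-stop/band-pass filtering,
spherical-spline interpolation of missing electrodes, average
re-referencing, trimming/baselining, global mean field amplitude
(GMFA), windowed peak extraction, and ROI selection by a grand-average
magnitude criterion.

Channel cleaning here replaces toolbox-specific automated routines
(clean_rawdata-style detectors and the SOUND noise-suppression
algorithm) with a defined variance/flatline/correlation rule plus
spherical-spline interpolation; the substitution is recorded in each
Epochs object's provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .containers import Epochs

#: Default peak specs: (label, polarity, nominal latency ms, window ms).
#: Windows are anchored to the conventional early/mid/late partition of
#: the evoked response at 75, 130 and 240 ms.
DEFAULT_PEAK_SPECS = (
    ("P30", +1, 30.0, (20.0, 40.0)),
    ("N45", -1, 45.0, (35.0, 55.0)),
    ("P60", +1, 60.0, (50.0, 75.0)),
    ("N100", -1, 100.0, (75.0, 130.0)),
    ("P180", +1, 180.0, (130.0, 240.0)),
    ("N280", -1, 280.0, (240.0, 320.0)),
)

#: GMFA search windows (label, window ms) for the five maxima the global
#: field typically shows; GMFA is unsigned so polarity does not apply.
GMFA_WINDOWS = (
    ("early1", (20.0, 45.0)),
    ("early2", (45.0, 75.0)),
    ("mid", (75.0, 130.0)),
    ("late", (130.0, 240.0)),
    ("n280", (240.0, 320.0)),
)


@dataclass(frozen=True)
class PeakSpec:
    label: str
    polarity: int  # +1 positive peak, -1 negative
    nominal_latency: float  # ms
    window: tuple[float, float]  # ms, closed interval

    def __post_init__(self):
        lo, hi = self.window
        if not lo <= self.nominal_latency <= hi:
            raise ValueError("nominal latency must lie inside the search window")
        if self.polarity not in (-1, +1):
            raise ValueError("polarity must be +1 or -1")


def default_peak_specs() -> list[PeakSpec]:
    return [PeakSpec(l, p, n, w) for l, p, n, w in DEFAULT_PEAK_SPECS]


@dataclass
class RoiSelection:
    labels: list
    threshold: float  # uV
    peak_times_ms: list
    empty: bool = False


# ---------------------------------------------------------------------------
# artifact excision


def excise_artifact(epochs: Epochs, window=(-8.0, 15.0), n_anchor: int = 5) -> Epochs:
    """Replace the pulse-artifact window with cubic interpolation.

    Samples inside the closed window are replaced, per channel and trial,
    by a cubic polynomial fitted to ``n_anchor`` samples on each side of
    the window; all other samples are untouched.
    """
    lo, hi = window
    out = epochs.copy()
    t = out.times
    if lo < t[0] or hi > t[-1]:
        raise ValueError("artifact window outside the epoch")
    inside = (t >= lo) & (t <= hi)
    if not inside.any():
        out.log("excise_artifact", window=list(window), n_samples=0)
        return out
    i0 = int(np.argmax(inside))
    i1 = int(len(t) - np.argmax(inside[::-1]))  # one past last inside sample
    left = np.arange(max(i0 - n_anchor, 0), i0)
    right = np.arange(i1, min(i1 + n_anchor, len(t)))
    anchors = np.concatenate([left, right])
    if anchors.size < 4:
        raise ValueError("not enough anchor samples outside the window")
    # cubic LS fit shared across channels/trials: coef = pinv(A) @ y
    tc = t[anchors] - t[inside].mean()  # center for conditioning
    A = np.vander(tc, 4)
    pinv = np.linalg.pinv(A)
    ti = t[inside] - t[inside].mean()
    Ai = np.vander(ti, 4)
    y = out.data[:, anchors, :]  # (ch, anchors, trials)
    coef = np.einsum("ka,cat->ckt", pinv, y)  # (ch, 4, trials)
    out.data[:, inside, :] = np.einsum("ik,ckt->cit", Ai, coef)
    out.log("excise_artifact", window=list(window), n_samples=int(inside.sum()))
    return out


# ---------------------------------------------------------------------------
# trial rejection


def _trial_logprob(data: np.ndarray, n_bins: int = 100):
    """Histogram-based per-trial, per-channel joint log-probability.

    For each channel, the empirical value distribution is estimated over
    all samples and trials; a trial's statistic on that channel is the
    mean log density of its samples.
    """
    n_ch, n_samp, n_trials = data.shape
    logp = np.empty((n_ch, n_trials))
    for c in range(n_ch):
        vals = data[c].ravel()
        hist, edges = np.histogram(vals, bins=n_bins, density=True)
        hist = np.maximum(hist, 1e-12)
        idx = np.clip(np.digitize(data[c], edges) - 1, 0, n_bins - 1)
        logp[c] = np.log(hist)[idx].mean(axis=0)
    return logp


def _jointprob_once(data: np.ndarray, sd_local: float, sd_global: float) -> np.ndarray:
    logp = _trial_logprob(data)  # (ch, trials)
    rej = np.zeros(data.shape[2], dtype=bool)
    # local: z-score per channel across trials
    mu = logp.mean(axis=1, keepdims=True)
    sd = logp.std(axis=1, keepdims=True)
    ok = sd.squeeze(1) > 0
    if ok.any():
        z = np.zeros_like(logp)
        z[ok] = (logp[ok] - mu[ok]) / sd[ok]
        rej |= (np.abs(z) > sd_local).any(axis=0)
    # global: z-score of the channel-summed statistic
    g = logp.sum(axis=0)
    if g.std() > 0:
        zg = (g - g.mean()) / g.std()
        rej |= np.abs(zg) > sd_global
    return rej


def reject_trials_jointprob(epochs: Epochs, sd_local: float = 3.3, sd_global: float = 3.3, min_trials: int = 10):
    """Joint-probability trial rejection, iterated once.

    A trial is removed when its per-channel (local) or all-channel
    (global) joint log-probability lies beyond the SD limit of the
    empirical distribution across trials. Returns (epochs, rejected
    trial indices); raises if fewer than ``min_trials`` trials survive.
    """
    out = epochs.copy()
    keep_idx = np.flatnonzero(~out.bad_trials)
    if keep_idx.size < min_trials:
        raise ValueError("too few retained trials for rejection")
    data = out.data[:, :, keep_idx]
    rej1 = _jointprob_once(data, sd_local, sd_global)
    # iterate once: recompute the distribution without first-pass rejects
    remaining = keep_idx[~rej1]
    rej2 = np.zeros(remaining.size, dtype=bool)
    if remaining.size >= 2 and rej1.any():
        rej2 = _jointprob_once(out.data[:, :, remaining], sd_local, sd_global)
    rejected = np.concatenate([keep_idx[rej1], remaining[rej2]])
    rejected = np.unique(rejected.astype(int))
    if keep_idx.size - rejected.size < min_trials:
        raise ValueError(
            f"only {keep_idx.size - rejected.size} trials would remain "
            f"(minimum {min_trials})"
        )
    out.bad_trials[rejected] = True
    out.log("reject_trials_jointprob", sd_local=sd_local, sd_global=sd_global,
            n_rejected=int(rejected.size), rejected=[int(i) for i in rejected])
    return out, rejected


# ---------------------------------------------------------------------------
# filtering


def filter_epochs(epochs: Epochs, bandstop=(57.0, 63.0), bandpass=(1.0, 100.0), order: int = 4) -> Epochs:
    """Zero-phase band-stop then band-pass filtering (Butterworth, filtfilt)."""
    out = epochs.copy()
    nyq = out.srate / 2.0
    for band in (bandstop, bandpass):
        if band is not None and max(band) >= nyq:
            raise ValueError("band edge at or above Nyquist")
    if out.srate < 250:
        raise ValueError("sampling rate too low for the default bands")
    x = out.data
    if bandstop is not None:
        sos = signal.butter(order, bandstop, btype="bandstop", fs=out.srate, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=1)
    if bandpass is not None:
        sos = signal.butter(order, bandpass, btype="bandpass", fs=out.srate, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=1)
    out.data = np.ascontiguousarray(x)
    out.log("filter_epochs", bandstop=list(bandstop) if bandstop else None,
            bandpass=list(bandpass) if bandpass else None, order=order)
    return out


# ---------------------------------------------------------------------------
# channel cleaning


def detect_bad_channels(epochs: Epochs, var_z: float = 5.0, corr_min: float = 0.4,
                        flat_uv: float = 1e-8) -> list:
    """Flag bad channels by variance, flatline, and neighbor correlation.

    A channel is flagged if (a) the robust z-score (median/MAD) of its
    log total variance exceeds ``var_z``, (b) it is flat (variance below
    ``flat_uv``), or (c) its maximal absolute correlation with any other
    channel falls below ``corr_min``. Stands in for toolbox automated
    channel-cleaning routines.
    """
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    x = epochs.data.reshape(epochs.n_channels, -1)
    var = x.var(axis=1)
    flagged = set()
    flat = var <= flat_uv
    flagged |= set(np.flatnonzero(flat))
    live = ~flat
    if live.sum() >= 3:
        logv = np.log(var[live])
        med = np.median(logv)
        mad = np.median(np.abs(logv - med))
        if mad > 0:
            rz = 0.6745 * (logv - med) / mad
            flagged |= set(np.flatnonzero(live)[np.abs(rz) > var_z])
    if live.sum() >= 2:
        xi = x[live]
        xi = xi - xi.mean(axis=1, keepdims=True)
        sd = xi.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        corr = (xi / sd) @ (xi / sd).T / xi.shape[1]
        np.fill_diagonal(corr, 0.0)
        max_corr = np.abs(corr).max(axis=1)
        flagged |= set(np.flatnonzero(live)[max_corr < corr_min])
    labels = [epochs.ch_names[i] for i in sorted(flagged)]
    epochs.log("detect_bad_channels", var_z=var_z, corr_min=corr_min, flagged=labels,
               note="variance/flatline/correlation rule standing in for automated toolbox cleaning")
    return labels


# ---------------------------------------------------------------------------
# spherical spline interpolation


def _g_matrix(cosang: np.ndarray, order: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(cos angle) with stiffness ``order``."""
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** order * (n + 1.0) ** order)
    shape = cosang.shape
    x = cosang.ravel()
    P = np.stack([eval_legendre(k, x) for k in n], axis=0)  # (n_terms, N)
    return ((coef[:, None] * P).sum(axis=0) / (4 * np.pi)).reshape(shape)


def spherical_spline_weights(good_pos: np.ndarray, bad_pos: np.ndarray,
                             order: int = 4, reg: float = 1e-5) -> np.ndarray:
    """Interpolation weight matrix W so that v_bad = W @ v_good.

    Spherical-spline interpolation with stiffness ``order`` and ridge
    regularization ``reg`` on the kernel matrix; exact for spatially
    constant fields by construction (the constant term is unpenalized).
    """
    cos_gg = np.clip(good_pos @ good_pos.T, -1, 1)
    cos_bg = np.clip(bad_pos @ good_pos.T, -1, 1)
    G = _g_matrix(cos_gg, order=order)
    Gb = _g_matrix(cos_bg, order=order)
    n = G.shape[0]
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    Ainv = np.linalg.pinv(A)
    # v_bad = [Gb, 1] @ Ainv @ [v_good; 0]
    B = np.hstack([Gb, np.ones((Gb.shape[0], 1))])
    return (B @ Ainv)[:, :n]


def interpolate_spherical(epochs: Epochs, missing_labels, order: int = 4, reg: float = 1e-5) -> Epochs:
    """Reconstruct missing channels by spherical-spline interpolation.

    Good channels are untouched; each missing channel is rebuilt from
    all remaining good channels and unmarked as bad.
    """
    out = epochs.copy()
    if not missing_labels:
        out.log("interpolate_spherical", missing=[])
        return out
    if out.montage is None:
        raise ValueError("montage required for spherical interpolation")
    miss_idx = [out.ch_names.index(l) for l in missing_labels]
    good_idx = [i for i in range(out.n_channels) if i not in miss_idx]
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    W = spherical_spline_weights(
        out.montage.positions[good_idx], out.montage.positions[miss_idx],
        order=order, reg=reg,
    )
    good = out.data[good_idx]  # (g, samples, trials)
    out.data[miss_idx] = np.einsum("bg,gst->bst", W, good)
    out.bad_channels[miss_idx] = False
    out.log("interpolate_spherical", missing=list(missing_labels), order=order, reg=reg,
            note="spherical-spline interpolation standing in for toolbox noise suppression")
    return out


# ---------------------------------------------------------------------------
# referencing, trimming, baselining


def rereference_average(epochs: Epochs) -> Epochs:
    """Re-reference to the instantaneous global channel average."""
    if epochs.n_channels < 2:
        raise ValueError("average reference undefined for a single channel")
    out = epochs.copy()
    out.data = out.data - out.data.mean(axis=0, keepdims=True)
    out.log("rereference_average")
    return out


def trim_baseline(epochs: Epochs, window=(-400.0, 400.0), baseline=(-400.0, -10.0)) -> Epochs:
    """Trim to the analysis window and subtract the per-channel baseline mean."""
    out = epochs.copy()
    keep = out.time_mask(*window)
    if not keep.any():
        raise ValueError("trim window outside the epoch")
    out.data = np.ascontiguousarray(out.data[:, keep, :])
    out.times = out.times[keep]
    bl = out.time_mask(*baseline)
    if not bl.any():
        raise ValueError("baseline window outside the trimmed epoch")
    out.data = out.data - out.data[:, bl, :].mean(axis=1, keepdims=True)
    out.log("trim_baseline", window=list(window), baseline=list(baseline))
    return out


# ---------------------------------------------------------------------------
# GMFA, peaks, ROI


def gmfa(erp: np.ndarray) -> np.ndarray:
    """Global mean field amplitude of a channels x samples array.

    Per-sample spatial standard deviation: the RMS deviation of channel
    values from the instantaneous channel mean.
    """
    erp = np.asarray(erp, dtype=float)
    if erp.ndim != 2:
        raise ValueError("erp must be channels x samples")
    return erp.std(axis=0, ddof=0)


def find_peaks(series: np.ndarray, times: np.ndarray, specs) -> dict:
    """Windowed extraction of local extrema of the requested polarity.

    For each spec, returns the latency (ms) of the local extremum of
    matching polarity with the largest magnitude inside the closed
    search window, or None if no local extremum exists there. Ties in
    magnitude break toward the earlier latency. Window endpoints only
    count as extrema relative to their inside neighbor.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    results = {}
    for spec in specs:
        lo, hi = spec.window
        win = np.flatnonzero((times >= lo) & (times <= hi))
        if win.size < 3:
            results[spec.label] = None
            continue
        y = spec.polarity * series
        best_idx, best_val = None, -np.inf
        for j in win:
            if j == 0 or j == len(series) - 1:
                continue
            if y[j] >= y[j - 1] and y[j] >= y[j + 1] and (y[j] > y[j - 1] or y[j] > y[j + 1]):
                if y[j] > best_val:
                    best_val, best_idx = y[j], j
        results[spec.label] = None if best_idx is None else float(times[best_idx])
    return results


def select_roi(grand_average: np.ndarray, times: np.ndarray, ch_names,
               peak_latencies_ms, threshold: float = 2.0) -> RoiSelection:
    """Electrodes with |grand-average| >= threshold at all peak timepoints."""
    ga = np.asarray(grand_average, dtype=float)
    idx = [int(np.argmin(np.abs(times - t))) for t in peak_latencies_ms]
    mask = np.ones(ga.shape[0], dtype=bool)
    for i in idx:
        mask &= np.abs(ga[:, i]) >= threshold
    labels = [c for c, m in zip(ch_names, mask) if m]
    return RoiSelection(labels=labels, threshold=threshold,
                        peak_times_ms=list(peak_latencies_ms), empty=not labels)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class PipelineConfig:
    artifact_window: tuple = (-8.0, 15.0)
    sd_local: float = 3.3
    sd_global: float = 3.3
    bandstop: tuple = (57.0, 63.0)
    bandpass: tuple = (1.0, 100.0)
    trim_window: tuple = (-400.0, 400.0)
    baseline: tuple = (-400.0, -10.0)
    roi_threshold: float = 2.0
    min_trials: int = 10


def preprocess(epochs: Epochs, config: PipelineConfig | None = None) -> Epochs:
    """Run the full preprocessing chain in the standard order.

    Artifact excision -> bad-channel detection -> joint-probability trial
    rejection -> filtering -> spherical interpolation of bad channels ->
    average reference -> trim + baseline.
    """
    cfg = config or PipelineConfig()
    ep = excise_artifact(epochs, window=cfg.artifact_window)
    bad = detect_bad_channels(ep)
    for lab in bad:
        ep.bad_channels[ep.ch_names.index(lab)] = True
    # rejection statistics computed on retained channels only
    sub = ep.copy()
    if bad:
        good_idx = np.flatnonzero(~ep.bad_channels)
        sub.data = ep.data[good_idx]
        sub.ch_names = tuple(ep.ch_names[i] for i in good_idx)
        sub.bad_channels = ep.bad_channels[good_idx]
        sub.montage = None
    _, rejected = reject_trials_jointprob(sub, cfg.sd_local, cfg.sd_global, cfg.min_trials)
    ep.bad_trials[rejected] = True
    ep.log("reject_trials_jointprob", n_rejected=int(len(rejected)),
           rejected=[int(i) for i in rejected])
    ep = filter_epochs(ep, bandstop=cfg.bandstop, bandpass=cfg.bandpass)
    if bad:
        ep = interpolate_spherical(ep, bad)
    ep = rereference_average(ep)
    ep = trim_baseline(ep, window=cfg.trim_window, baseline=cfg.baseline)
    return ep


def gmfa_peaks(epochs: Epochs, windows=GMFA_WINDOWS) -> dict:
    """GMFA of the trial average and its windowed maxima (label -> ms)."""
    g = gmfa(epochs.average())
    specs = [PeakSpec(lab, +1, (w[0] + w[1]) / 2, w) for lab, w in windows]
    return find_peaks(g, epochs.times, specs)
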