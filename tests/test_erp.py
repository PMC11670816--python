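"""ERP preprocessing and summarization operations."""

import numpy as np
import pytest

from coilcomp import erp, simulate
from coilcomp.containers import Epochs
from coilcomp.erp import (
    PeakSpec,
    excise_artifact,
    detect_bad_channels,
    filter_epochs,
    find_peaks,
    gmfa,
    interpolate_spherical,
    reject_trials_jointprob,
    rereference_average,
    select_roi,
    spherical_spline_weights,
    trim_baseline,
)


def make_epochs(data, srate=1000.0, t0=None, montage=None):
    n_ch, n_samp, _ = data.shape
    t0 = -n_samp // 2 if t0 is None else t0
    times = (np.arange(n_samp) + t0) * 1000.0 / srate
    names = tuple(montage.labels) if montage is not None else tuple(f"E{i+1}" for i in range(n_ch))
    return Epochs(np.asarray(data, float), srate, times, names, montage=montage)


class TestExciseArtifact:
    def test_linear_ramp_exactly_restored(self):
        t = np.arange(-100, 101)
        data = np.tile((2.0 * t + 3.0)[None, :, None], (3, 1, 2))
        ep = make_epochs(data, t0=-100)
        out = excise_artifact(ep, window=(-8, 15))
        assert np.allclose(out.data, data, atol=1e-9)

    def test_constant_signal_unchanged(self):
        data = np.full((4, 200, 3), 7.5)
        ep = make_epochs(data)
        out = excise_artifact(ep)
        assert np.allclose(out.data, 7.5)

    def test_spike_removed_and_bounded(self):
        rng = np.random.default_rng(0)
        data = 0.1 * rng.standard_normal((2, 300, 4))
        ep = make_epochs(data, t0=-150)
        w = (ep.times >= 0) & (ep.times <= 10)
        ep.data[:, w, :] += 5000.0
        out = excise_artifact(ep, window=(-8, 15))
        inside = (out.times >= -8) & (out.times <= 15)
        near = ((out.times >= -30) & (out.times < -8)) | ((out.times > 15) & (out.times <= 37))
        assert np.abs(out.data[:, inside, :]).max() <= 10 * np.abs(out.data[:, near, :]).max() + 1.0
        # samples outside the window are bit-identical
        assert np.array_equal(out.data[:, ~inside, :], ep.data[:, ~inside, :])

    def test_window_outside_epoch_rejected(self):
        ep = make_epochs(np.zeros((2, 50, 2)), t0=-25)
        with pytest.raises(ValueError):
            excise_artifact(ep, window=(-8, 100))


class TestJointProbRejection:
    def test_identical_trials_not_rejected(self):
        one = np.sin(np.linspace(0, 10, 200))
        data = np.tile(one[None, :, None], (4, 1, 30))
        ep = make_epochs(data)
        out, rej = reject_trials_jointprob(ep)
        assert rej.size == 0

    def test_single_huge_trial_rejected(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((6, 150, 200))
        data[:, :, 77] *= 100.0
        ep = make_epochs(data)
        out, rej = reject_trials_jointprob(ep)
        assert 77 in rej
        assert out.bad_trials[77]

    def test_matches_bruteforce_recomputation(self):
        """Rejected set equals an independent plain-loop recomputation."""
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 80, 60))
        data[:, :, 10] += 8.0
        data[2, :, 33] *= 30.0
        ep = make_epochs(data)
        _, rej = reject_trials_jointprob(ep, sd_local=3.3, sd_global=3.3)

        def brute_once(x):
            n_ch, n_s, n_t = x.shape
            logp = np.zeros((n_ch, n_t))
            for c in range(n_ch):
                hist, edges = np.histogram(x[c].ravel(), bins=100, density=True)
                hist = np.maximum(hist, 1e-12)
                for t in range(n_t):
                    idx = np.clip(np.digitize(x[c, :, t], edges) - 1, 0, 99)
                    logp[c, t] = np.mean(np.log(hist[idx]))
            rej = np.zeros(n_t, bool)
            for c in range(n_ch):
                sd = logp[c].std()
                if sd > 0:
                    rej |= np.abs((logp[c] - logp[c].mean()) / sd) > 3.3
            g = logp.sum(axis=0)
            if g.std() > 0:
                rej |= np.abs((g - g.mean()) / g.std()) > 3.3
            return rej

        r1 = brute_once(data)
        remaining = np.flatnonzero(~r1)
        r2 = brute_once(data[:, :, remaining])
        expected = np.unique(np.concatenate([np.flatnonzero(r1), remaining[r2]]))
        assert np.array_equal(np.sort(rej), expected)

    def test_too_few_trials_raises(self):
        ep = make_epochs(np.random.default_rng(0).standard_normal((3, 50, 5)))
        with pytest.raises(ValueError):
            reject_trials_jointprob(ep)


class TestFilterEpochs:
    def _tone(self, freq, srate=1000.0, n=2000, n_ch=2, n_tr=2):
        t = np.arange(n) / srate
        x = np.sin(2 * np.pi * freq * t)
        return make_epochs(np.tile(x[None, :, None], (n_ch, 1, n_tr)), srate=srate)

    def test_line_frequency_strongly_attenuated(self):
        ep = self._tone(60.0)
        out = filter_epochs(ep)
        mid = slice(500, 1500)  # avoid edge transients
        assert np.mean(out.data[0, mid, 0] ** 2) <= 0.01 * np.mean(ep.data[0, mid, 0] ** 2)

    def test_passband_preserved(self):
        ep = self._tone(10.0)
        out = filter_epochs(ep)
        mid = slice(500, 1500)
        ratio = out.data[0, mid, 0].std() / ep.data[0, mid, 0].std()
        assert 0.9 <= ratio <= 1.1

    def test_dc_offset_removed(self):
        ep = make_epochs(np.full((2, 3000, 2), 10.0))
        out = filter_epochs(ep)
        assert np.abs(out.data[:, 1000:2000, :]).max() < 0.5

    def test_band_above_nyquist_rejected(self):
        ep = self._tone(10.0, srate=300.0)
        with pytest.raises(ValueError):
            filter_epochs(ep, bandpass=(1.0, 200.0))


class TestBadChannelDetection:
    def test_identical_channels_clean(self):
        one = np.sin(np.linspace(0, 20, 300))
        data = np.tile(one[None, :, None], (6, 1, 10))
        ep = make_epochs(data)
        assert detect_bad_channels(ep) == []

    def test_flatline_flagged(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((5, 200, 10))
        common = np.sin(np.linspace(0, 30, 200))
        data += 3 * common[None, :, None]
        data[2] = 0.0
        ep = make_epochs(data)
        assert "E3" in detect_bad_channels(ep)

    def test_uncorrelated_noise_channel_flagged(self):
        rng = np.random.default_rng(4)
        common = rng.standard_normal((1, 400, 20))
        data = np.tile(common, (8, 1, 1)) + 0.05 * rng.standard_normal((8, 400, 20))
        data[5] = rng.standard_normal((400, 20))  # shares nothing with the rest
        ep = make_epochs(data)
        assert "E6" in detect_bad_channels(ep)

    def test_single_channel_rejected(self):
        ep = make_epochs(np.zeros((1, 50, 2)))
        with pytest.raises(ValueError):
            detect_bad_channels(ep)


class TestSphericalInterpolation:
    def test_constant_field_reproduced(self, montage16):
        data = np.full((16, 40, 3), 4.2)
        ep = make_epochs(data, montage=montage16)
        ep.data[5] = 0.0
        out = interpolate_spherical(ep, ["E6"])
        assert np.allclose(out.data[5], 4.2, atol=1e-6)
        # untouched channels bit-identical
        assert np.array_equal(out.data[0], ep.data[0])

    def test_leave_one_out_on_dipolar_field(self, montage63):
        """A smooth dipolar field is recovered within 15% relative error."""
        d = np.array([0.3, -0.2, 0.93])
        field = montage63.positions @ d  # linear in position: spatially smooth
        data = np.tile(field[:, None, None], (1, 10, 2))
        ep = make_epochs(data, montage=montage63)
        held = 20  # interior electrode
        truth = field[held]
        ep.data[held] = 0.0
        out = interpolate_spherical(ep, [montage63.labels[held]])
        err = np.abs(out.data[held] - truth) / np.abs(truth)
        assert err.max() < 0.15

    def test_empty_missing_set_is_identity(self, montage16):
        rng = np.random.default_rng(5)
        ep = make_epochs(rng.standard_normal((16, 30, 2)), montage=montage16)
        out = interpolate_spherical(ep, [])
        assert np.array_equal(out.data, ep.data)

    def test_too_few_channels_raises(self, montage16):
        ep = make_epochs(np.zeros((16, 20, 1)), montage=montage16)
        with pytest.raises(ValueError):
            interpolate_spherical(ep, list(montage16.labels[:14]))

    def test_weights_sum_to_one(self, montage63):
        """Constant reproduction implies unit row sums of the weight matrix."""
        W = spherical_spline_weights(montage63.positions[:-3], montage63.positions[-3:])
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-6)


class TestReferenceAndBaseline:
    def test_average_reference_zero_mean(self):
        rng = np.random.default_rng(6)
        ep = make_epochs(rng.standard_normal((7, 60, 4)) + 5)
        out = rereference_average(ep)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_zero_mean_data_unchanged(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((5, 40, 3))
        data -= data.mean(axis=0, keepdims=True)
        ep = make_epochs(data)
        out = rereference_average(ep)
        assert np.allclose(out.data, data)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_average(make_epochs(np.zeros((1, 30, 2))))

    def test_baseline_zeroed_and_time_alignment_kept(self):
        data = np.full((3, 2001, 2), 3.3)
        ep = make_epochs(data, t0=-1000)
        out = trim_baseline(ep)
        assert np.allclose(out.data, 0.0)
        bl = out.time_mask(-400, -10)
        assert np.abs(out.data[:, bl, :].mean(axis=1)).max() < 1e-10
        assert 0.0 in out.times
        assert out.times[0] >= -400 and out.times[-1] <= 400


class TestGMFA:
    def test_uniform_field_is_zero(self):
        assert np.allclose(gmfa(np.full((5, 30), 2.0)), 0.0)

    def test_two_channel_closed_form(self):
        a = np.linspace(0, 3, 20)
        erp_mat = np.vstack([a, -a])
        assert np.allclose(gmfa(erp_mat), a)

    def test_matches_bruteforce_formula(self, rng):
        x = rng.standard_normal((4, 6))
        expected = np.empty(6)
        for s in range(6):
            m = x[:, s].mean()
            expected[s] = np.sqrt(np.mean((x[:, s] - m) ** 2))
        assert np.allclose(gmfa(x), expected)


class TestFindPeaks:
    def _times(self, n=401):
        return np.arange(n, dtype=float)  # 0..400 ms at 1 kHz

    def test_monotone_series_has_no_peaks(self):
        t = self._times()
        res = find_peaks(t * 0.01, t, erp.default_peak_specs())
        assert all(v is None for v in res.values())

    def test_gaussian_bump_found_at_latency(self):
        t = self._times()
        y = 5 * np.exp(-0.5 * ((t - 186) / 20) ** 2)
        spec = PeakSpec("P180", +1, 180.0, (130.0, 240.0))
        res = find_peaks(y, t, [spec])
        assert res["P180"] == pytest.approx(186.0, abs=1.0)

    def test_larger_of_two_bumps_wins(self):
        t = self._times()
        y = 3 * np.exp(-0.5 * ((t - 150) / 8) ** 2) + 5 * np.exp(-0.5 * ((t - 210) / 8) ** 2)
        res = find_peaks(y, t, [PeakSpec("P180", +1, 180.0, (130.0, 240.0))])
        assert res["P180"] == pytest.approx(210.0, abs=1.0)

    def test_tie_breaks_earlier(self):
        t = self._times()
        y = np.exp(-0.5 * ((t - 150) / 8) ** 2) + np.exp(-0.5 * ((t - 210) / 8) ** 2)
        res = find_peaks(y, t, [PeakSpec("P180", +1, 180.0, (130.0, 240.0))])
        assert res["P180"] == pytest.approx(150.0, abs=1.0)

    def test_polarity_respected(self):
        t = self._times()
        y = -4 * np.exp(-0.5 * ((t - 100) / 10) ** 2)
        res = find_peaks(y, t, [PeakSpec("N100", -1, 100.0, (75.0, 130.0)),
                                PeakSpec("P60", +1, 60.0, (50.0, 75.0))])
        assert res["N100"] == pytest.approx(100.0, abs=1.0)
        assert res["P60"] is None


class TestSelectRoi:
    def test_zero_threshold_selects_everything(self):
        ga = np.ones((5, 100))
        times = np.arange(100, dtype=float)
        roi = select_roi(ga, times, [f"E{i}" for i in range(5)], [50.0], threshold=0.0)
        assert len(roi.labels) == 5

    def test_constructed_membership(self):
        times = np.arange(300, dtype=float)
        ga = np.zeros((10, 300))
        ga[:7, 100] = 2.5
        ga[:7, 186] = -2.1  # magnitude criterion is sign-free
        ga[7:, 100] = 1.0
        names = [f"E{i+1}" for i in range(10)]
        roi = select_roi(ga, times, names, [100.0, 186.0], threshold=2.0)
        assert roi.labels == names[:7]

    def test_unreachable_threshold_flags_empty(self):
        ga = np.ones((4, 50))
        roi = select_roi(ga, np.arange(50.0), list("abcd"), [10.0], threshold=1e9)
        assert roi.empty and roi.labels == []


class TestPipelineRoundTrip:
    def test_gain_scaling_increases_roi_deflection(self, montage16):
        """Doubling the late-component gains grows the response monotonically."""
        comp = (("N100", 100.0, 15.0, -8.0, 1, 0.5, 1.0),
                ("P180", 186.0, 25.0, 7.0, 1, 0.5, 1.0))
        spec = simulate.EEGSimSpec(montage=montage16, n_trials=30, components=comp,
                                   noise_1f_amp=0.5, line_noise_amp=0)
        lo = simulate.generate_epochs(spec, condition_gains={"N100": 1, "P180": 1}, seed=3)
        hi = simulate.generate_epochs(spec, condition_gains={"N100": 2, "P180": 2}, seed=3)
        g_lo = gmfa(trim_baseline(rereference_average(lo)).average())
        g_hi = gmfa(trim_baseline(rereference_average(hi)).average())
        t = trim_baseline(lo).times
        for lat in (100.0, 186.0):
            i = int(np.argmin(np.abs(t - lat)))
            assert g_hi[i] > g_lo[i]

    def test_provenance_accumulates(self, montage16):
        spec = simulate.EEGSimSpec(montage=montage16, n_trials=20, noise_1f_amp=1.0)
        ep = simulate.generate_epochs(spec, seed=0)
        clean = erp.preprocess(ep)
        ops = [e["operation"] for e in clean.provenance]
        for expected in ("generate_epochs", "excise_artifact", "detect_bad_channels",
                         "reject_trials_jointprob", "filter_epochs",
                         "rereference_average", "trim_baseline"):
            assert expected in ops
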