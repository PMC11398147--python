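import numpy as np
import pytest
from scipy import signal as sps

from accelsleep import extract as ex
from accelsleep import simulate as sim
from accelsleep.types import BeatSeries, GappedSeries, OrientationSignal, TriaxialAccel


def make_accel(x, y=None, z=None, fs=100.0):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
    return TriaxialAccel(fs=fs, x=x, y=y, z=z)


class TestCollapseChannels:
    def test_zeros(self):
        assert np.all(ex.collapse_channels(make_accel(np.zeros(10))) == 0)

    def test_arithmetic(self):
        a = make_accel([1, 2], [3, 4], [5, 6])
        assert np.array_equal(ex.collapse_channels(a), [9, 12])

    def test_linearity_of_integral(self):
        rng = np.random.default_rng(0)
        a = make_accel(rng.normal(size=50), rng.normal(size=50), rng.normal(size=50))
        s = ex.collapse_channels(a)
        assert s.sum() == pytest.approx(a.x.sum() + a.y.sum() + a.z.sum())


class TestActivityCounts:
    def test_constant_channels_zero(self):
        a = make_accel(np.ones(500), np.full(500, 2.0), np.full(500, -1.0))
        assert np.allclose(ex.activity_counts(a), 0.0)

    def test_alternating_channel(self):
        x = np.tile([1.0, -1.0], 100)  # zero-mean, |dev| = 1
        a = make_accel(x, np.ones(200), np.ones(200), fs=100.0)
        assert np.allclose(ex.activity_counts(a), 1.0)

    def test_matches_bruteforce_formula(self):
        rng = np.random.default_rng(1)
        fs = 50
        a = make_accel(rng.normal(size=fs * 20), rng.normal(size=fs * 20),
                       rng.normal(size=fs * 20), fs=fs)
        act = ex.activity_counts(a)
        for sec in range(20):
            expected = 0.0
            for ch in (a.x, a.y, a.z):
                w = ch[sec * fs:(sec + 1) * fs]
                expected += np.sum(np.abs(w - w.mean())) / fs
            assert act[sec] == pytest.approx(expected, rel=1e-12)

    def test_partial_trailing_second_dropped(self):
        a = make_accel(np.ones(250), fs=100.0)
        assert len(ex.activity_counts(a)) == 2


class TestComputeIhr:
    def test_basic_rate(self):
        beats = BeatSeries.from_times([0.0, 0.5, 1.0])
        ihr = ex.compute_ihr(beats)
        assert np.all(ihr.values[ihr.valid] == pytest.approx(120.0))

    def test_piecewise_constant_evaluation(self):
        beats = BeatSeries(np.array([0.0, 1.0]), np.array([1.0, 0.8]))
        ihr = ex.compute_ihr(beats, duration=1.8)
        t = ihr.t
        i55 = np.argmin(np.abs(t - 0.55))
        i105 = np.argmin(np.abs(t - 1.05))
        assert ihr.values[i55] == pytest.approx(60.0)
        assert ihr.values[i105] == pytest.approx(75.0)

    def test_change_points_only_at_beats(self):
        rng = np.random.default_rng(2)
        times = np.cumsum(rng.uniform(0.7, 1.2, size=40))
        beats = BeatSeries.from_times(times)
        ihr = ex.compute_ihr(beats, fs=100.0)
        v, ok, t = ihr.values, ihr.valid, ihr.t
        changes = t[1:][ok[1:] & ok[:-1] & (np.diff(v) != 0)]
        for tc in changes:
            assert np.min(np.abs(beats.times - tc)) < 1.0 / 100.0 + 1e-9

    def test_invalid_outside_coverage(self):
        beats = BeatSeries.from_times([5.0, 6.0, 7.0])
        ihr = ex.compute_ihr(beats, duration=10.0)
        assert not ihr.valid[ihr.t < 5.0].any()
        assert not ihr.valid[ihr.t >= 8.0].any()

    def test_empty_beats(self):
        ihr = ex.compute_ihr(BeatSeries.from_times(np.empty(0)), duration=5.0)
        assert not ihr.valid.any()


class TestMaskLowQuality:
    def test_all_good_unchanged(self):
        beats = BeatSeries.from_times(np.arange(0.0, 10.0), quality=np.ones(10))
        ihr = ex.compute_ihr(beats)
        out = ex.mask_low_quality(ihr, beats, 0.5)
        assert np.array_equal(out.valid, ihr.valid)

    def test_single_bad_beat_masks_its_hold_interval(self):
        q = np.ones(10)
        q[4] = 0.0
        beats = BeatSeries.from_times(np.arange(0.0, 10.0), quality=q)
        ihr = ex.compute_ihr(beats)
        out = ex.mask_low_quality(ihr, beats, 0.5)
        t = out.t
        in_hold = (t >= 4.0) & (t < 5.0)
        assert not out.valid[in_hold].any()
        assert np.array_equal(out.valid[~in_hold], ihr.valid[~in_hold])

    def test_zero_threshold_vacuous(self):
        beats = BeatSeries.from_times(np.arange(0.0, 10.0), quality=np.zeros(10))
        ihr = ex.compute_ihr(beats)
        out = ex.mask_low_quality(ihr, beats, 0.0)
        assert np.array_equal(out.valid, ihr.valid)


class TestDecimateAccel:
    def test_constant_preserved(self):
        a = make_accel(np.full(2500, 0.7), np.full(2500, -0.2), np.ones(2500), fs=250.0)
        d = ex.decimate_accel(a, 10.0)
        assert d.fs == 10.0
        assert np.allclose(d.x, 0.7, atol=1e-9)
        assert np.allclose(d.z, 1.0, atol=1e-9)

    def test_passband_amplitude(self):
        t = np.arange(0, 60, 1 / 250.0)
        a = make_accel(np.sin(2 * np.pi * 0.3 * t), fs=250.0)
        d = ex.decimate_accel(a, 10.0)
        assert np.abs(d.x[50:-50]).max() == pytest.approx(1.0, abs=0.01)

    def test_stopband_rejection(self):
        t = np.arange(0, 60, 1 / 250.0)
        a = make_accel(np.sin(2 * np.pi * 30.0 * t), fs=250.0)
        d = ex.decimate_accel(a, 10.0)
        assert np.abs(d.x[50:-50]).max() < 0.01

    def test_rejects_upsampling(self):
        a = make_accel(np.zeros(100), fs=10.0)
        with pytest.raises(ValueError):
            ex.decimate_accel(a, 20.0)


class TestToOrientation:
    def test_static_gravity_along_z(self):
        n = 600
        a = make_accel(np.zeros(n), np.zeros(n), np.ones(n), fs=10.0)
        o = ex.to_orientation(a)
        assert np.allclose(o.v, 1.0, atol=1e-9)
        assert np.allclose(o.h1, 0.0, atol=1e-9)
        assert np.allclose(o.h2, 0.0, atol=1e-9)

    def test_static_tilt_against_reference(self):
        th = np.deg2rad(5.0)
        n = 100
        a = make_accel(np.full(n, np.sin(th)), np.zeros(n), np.full(n, np.cos(th)),
                       fs=10.0)
        o = ex.to_orientation(a, gravity_ref=(0, 0, 1))
        assert np.allclose(np.sqrt(o.h1 ** 2 + o.h2 ** 2), np.sin(th), atol=1e-3)

    def test_unit_norm_invariant(self):
        rng = np.random.default_rng(3)
        a = make_accel(rng.normal(0, 0.1, 500), rng.normal(0, 0.1, 500),
                       1 + rng.normal(0, 0.1, 500), fs=10.0)
        o = ex.to_orientation(a)
        norm = o.h1 ** 2 + o.h2 ** 2 + o.v ** 2
        assert np.all(np.abs(norm[o.valid] - 1.0) < 1e-9)

    def test_near_zero_norm_invalid(self):
        x = np.zeros(100)
        z = np.ones(100)
        z[40:45] = 0.01  # free fall
        a = make_accel(x, np.zeros(100), z, fs=10.0)
        o = ex.to_orientation(a)
        assert not o.valid[40:45].any()
        assert o.valid[:40].all()


class TestEstimateEffort:
    def test_single_tone_recovery(self):
        t = np.arange(0, 600, 0.1)
        h1 = 0.05 * np.sin(2 * np.pi * 0.25 * t)
        o = OrientationSignal(h1=h1, h2=np.zeros_like(t), v=np.sqrt(1 - h1 ** 2),
                              valid=np.ones(len(t), bool))
        res = ex.estimate_effort(o)
        sl = slice(300, len(t) - 300)  # after filter transients
        c = np.corrcoef(res.values[sl], h1[sl])[0, 1]
        assert c > 0.99

    def test_constant_orientation_near_zero(self):
        n = 3000
        o = OrientationSignal(h1=np.full(n, 0.1), h2=np.full(n, -0.05),
                              v=np.full(n, np.sqrt(1 - 0.1 ** 2 - 0.05 ** 2)),
                              valid=np.ones(n, bool))
        res = ex.estimate_effort(o)
        assert np.abs(res.values).max() < 1e-6

    def test_recovers_configured_respiratory_rate(self):
        rec = sim.simulate_recording(sim.SleepArchitecture(n_epochs=40),
                                     seed=3, fs=100.0)
        acc10 = ex.decimate_accel(rec.accel, 10.0)
        res = ex.estimate_effort(ex.to_orientation(acc10))
        ok = tot = 0
        for e in range(40):
            t0, t1 = e * 30.0, (e + 1) * 30.0
            if any(s < t1 and en > t0 for s, en in rec.movement_intervals):
                continue
            x = res.values[e * 300:(e + 1) * 300]
            f, p = sps.periodogram(x - x.mean(), fs=10.0, nfft=4096)
            m = (f >= 0.1) & (f <= 0.7)
            fd = f[m][np.argmax(p[m])]
            cfg = rec.params.resp_rate[rec.hypnogram.labels[e]]
            tot += 1
            ok += abs(fd - cfg) <= 0.03
        assert tot > 10
        assert ok / tot >= 0.9


class TestMixEffort:
    def test_zero_activity_identity(self):
        res = GappedSeries(10.0, np.linspace(-1, 1, 100), np.ones(100, bool))
        out = ex.mix_effort(res, np.zeros(10), act_scale=4.0)
        assert np.array_equal(out.values, res.values)

    def test_arithmetic(self):
        res = GappedSeries(10.0, np.full(10, 0.8), np.ones(10, bool))
        out = ex.mix_effort(res, np.array([0.5]), act_scale=1.0)
        assert np.allclose(out.values, 1.2)

    def test_invalid_samples_stay_invalid(self):
        valid = np.ones(20, bool)
        valid[5:8] = False
        res = GappedSeries(10.0, np.ones(20), valid)
        out = ex.mix_effort(res, np.array([1.0, 1.0]), act_scale=2.0)
        assert not out.valid[5:8].any()

    def test_length_mismatch_rejected(self):
        res = GappedSeries(10.0, np.ones(100), np.ones(100, bool))
        with pytest.raises(ValueError, match="mismatch"):
            ex.mix_effort(res, np.zeros(50), act_scale=1.0)

    def test_movement_raises_resact_rms(self, short_recording):
        bundle = sim.bundle_from_truth(short_recording)
        t = bundle.resact.t
        inside = np.zeros(len(t), bool)
        for st, en in short_recording.movement_intervals:
            inside |= (t >= st) & (t < en)
        if inside.sum() > 20 and (~inside).sum() > 20:
            rms_in = np.sqrt(np.mean(bundle.resact.values[inside] ** 2))
            rms_out = np.sqrt(np.mean(bundle.resact.values[~inside] ** 2))
            assert rms_in > 3 * rms_out


class TestDetectHeartbeats:
    def test_clean_recording_recall(self, quiet_phys):
        rec = sim.simulate_recording(sim.SleepArchitecture(n_epochs=12),
                                     phys=quiet_phys, seed=8, fs=100.0)
        beats = ex.detect_heartbeats(ex.collapse_channels(rec.accel), 100.0)
        tb = rec.true_beats.times
        d = np.abs(tb[:, None] - beats.times[None, :]).min(axis=1)
        assert np.mean(d <= 0.05) >= 0.95
        idx = np.abs(tb[:, None] - beats.times[None, :]).argmin(axis=1)
        m = d <= 0.05
        ibi_err = np.abs(beats.ibis[idx[:-1][m[:-1]]] - rec.true_beats.ibis[:-1][m[:-1]])
        assert np.median(ibi_err) < 0.020

    def test_white_noise_low_quality(self):
        rng = np.random.default_rng(0)
        beats = ex.detect_heartbeats(rng.normal(0, 1, 60_000), 100.0)
        assert len(beats) == 0 or beats.quality.mean() < 0.3

    def test_all_zero_signal_empty(self):
        assert len(ex.detect_heartbeats(np.zeros(10_000), 100.0)) == 0

    def test_short_recording_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            beats = ex.detect_heartbeats(np.random.default_rng(1).normal(size=100),
                                         100.0)
        assert len(beats) == 0


def test_extract_bundle_end_to_end(short_recording):
    bundle, beats = ex.extract_bundle(short_recording.accel)
    n = bundle.n_samples
    assert len(bundle.ihr) == len(bundle.res) == len(bundle.resact) == n
    assert len(beats) > 500
    assert np.all(bundle.act >= 0)
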