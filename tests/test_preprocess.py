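import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synergait as sg
from synergait.datatypes import Cycle, EmgRecording, GaitTimeline, NormalizedCycleSet, Stride

RATE = 2000.0


def _rec(data, rate=RATE, channels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < data.shape[1]:
        data = data.T
    if channels is None:
        channels = [f"ch{i}" for i in range(data.shape[1])]
    return EmgRecording(channels=channels, rate=rate, data=data)


def _brute_force_interpolate(x, rate, sd_multiple=10.0, half_window=0.150):
    """Independent scan-and-merge reimplementation of spike interpolation."""
    w = int(round(half_window * rate))
    thr = sd_multiple * x.std()
    bad = np.zeros(x.size, dtype=bool)
    for i in np.flatnonzero(np.abs(x) > thr):
        bad[max(0, i - w):min(x.size, i + w + 1)] = True
    y = x.copy()
    i = 0
    while i < x.size:
        if bad[i]:
            j = i
            while j < x.size and bad[j]:
                j += 1
            left = x[i - 1] if i > 0 else None
            right = x[j] if j < x.size else None
            if left is None and right is None:
                pass
            elif left is None:
                y[i:j] = right
            elif right is None:
                y[i:j] = left
            else:
                y[i:j] = np.interp(np.arange(i, j), [i - 1, j], [left, right])
            i = j
        else:
            i += 1
    return y


class TestInterpolateArtifacts:
    def test_clean_signal_unchanged(self):
        t = np.arange(0, 1, 1 / RATE)
        rec = _rec(np.sin(2 * np.pi * 40 * t))
        out = sg.interpolate_artifacts(rec)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_single_spike_replaced_by_straight_line(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(8000)
        i = 4000
        x[i] = 25 * x.std()
        out = sg.interpolate_artifacts(_rec(x)).data[:, 0]
        w = int(round(0.150 * RATE))
        seg = out[i - w:i + w + 1]
        line = np.linspace(x[i - w - 1], x[i + w + 1], seg.size + 2)[1:-1]
        np.testing.assert_allclose(seg, line, atol=1e-12)
        # everything outside the epoch untouched
        np.testing.assert_array_equal(out[:i - w], x[:i - w])
        np.testing.assert_array_equal(out[i + w + 1:], x[i + w + 1:])

    def test_overlapping_spikes_match_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(6000)
        for i in (1000, 1200, 1350, 5900):  # overlapping epochs + boundary clamp
            x[i] = 30 * x.std()
        thr_x = x.copy()
        out = sg.interpolate_artifacts(_rec(thr_x)).data[:, 0]
        expect = _brute_force_interpolate(x, RATE)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_no_sample_above_threshold_after_replacement(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(6000)
        idx = rng.integers(0, 6000, 5)
        x[idx] = 20 * x.std() * np.sign(rng.standard_normal(5))
        out = sg.interpolate_artifacts(_rec(x)).data[:, 0]
        assert np.all(np.abs(out) <= 10 * x.std())


class TestFilterEmg:
    def test_stopband_passband_and_notch(self):
        t = np.arange(0, 4, 1 / RATE)
        for freq, check in [(5.0, lambda a: a <= 0.05),
                            (100.0, lambda a: 0.95 <= a <= 1.05),
                            (50.0, lambda a: a <= 0.1)]:  # >= 20 dB down
            rec = _rec(np.sin(2 * np.pi * freq * t))
            out = sg.filter_emg(rec).data[2000:-2000, 0]
            amp = np.abs(out).max()
            assert check(amp), f"{freq} Hz -> amplitude {amp}"

    def test_zero_phase_pulse_peak_preserved(self):
        x = np.zeros(8000)
        x[4000] = 1.0
        out = sg.filter_emg(_rec(x)).data[:, 0]
        assert np.argmax(np.abs(out)) == 4000


class TestEnvelope:
    def test_constant_tone_gives_constant_amplitude(self):
        t = np.arange(0, 3, 1 / RATE)
        rec = _rec(2.5 * np.cos(2 * np.pi * 80 * t))
        env = sg.envelope(rec).data[2000:-2000, 0]
        np.testing.assert_allclose(env, 2.5, rtol=0.02)

    def test_zero_in_zero_out(self):
        env = sg.envelope(_rec(np.zeros(4000))).data
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_tracks_slow_amplitude_modulation(self):
        t = np.arange(0, 5, 1 / RATE)
        m = 1.0 + 0.8 * np.sin(2 * np.pi * 1.5 * t)
        carrier = np.cos(2 * np.pi * 120 * t)
        env = sg.envelope(_rec(m * carrier)).data[2000:-2000, 0]
        r = np.corrcoef(np.abs(m)[2000:-2000], env)[0, 1]
        assert r >= 0.99

    def test_output_nonnegative(self, rng):
        rec = _rec(rng.standard_normal(5000))
        assert np.all(sg.envelope(sg.filter_emg(rec)).data >= 0)


def _timeline(strides):
    events = []
    for s in strides:
        events.append((s.start, "right", "strike"))
    events.append((strides[-1].end, "right", "strike"))
    tl = GaitTimeline(events=events)
    tl.strides = strides
    return tl


class TestTimeNormalize:
    def test_identity_on_matching_ramp(self):
        # stride of exactly 200 samples holding a linear ramp
        rate = 200.0
        ramp = np.arange(200, dtype=float)
        rec = EmgRecording(channels=["a"], rate=rate, data=ramp[:, None])
        tl = _timeline([Stride(start=0.0, end=1.0, stride_id=0, valid=True)])
        out = sg.time_normalize(rec, tl)
        np.testing.assert_allclose(out.cycles[0].data[:, 0], ramp, atol=1e-9)

    def test_first_point_is_strike_sample(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 777)
        rec = EmgRecording(channels=["a"], rate=1000.0, data=x[:, None])
        tl = _timeline([Stride(start=0.1, end=0.6, stride_id=0, valid=True)])
        out = sg.time_normalize(rec, tl)
        assert out.cycles[0].data[0, 0] == pytest.approx(x[100], abs=1e-12)

    def test_matches_brute_force_piecewise_linear(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 2, 3000)
        rate = 1000.0
        rec = EmgRecording(channels=["a"], rate=rate, data=x[:, None])
        start, end = 0.313, 1.877
        tl = _timeline([Stride(start=start, end=end, stride_id=0, valid=True)])
        out = sg.time_normalize(rec, tl).cycles[0].data[:, 0]
        t_grid = np.arange(x.size) / rate
        expect = np.empty(200)
        for i in range(200):  # brute-force piecewise-linear evaluation
            q = start + i / 200 * (end - start)
            j = int(np.floor(q * rate))
            frac = q * rate - j
            expect[i] = x[j] * (1 - frac) + x[j + 1] * frac
        np.testing.assert_allclose(out, expect, atol=1e-12)
        assert t_grid[0] == 0.0

    def test_out_of_range_stride_skipped(self):
        rec = EmgRecording(channels=["a"], rate=1000.0, data=np.ones((1000, 1)))
        tl = _timeline([Stride(start=0.1, end=0.5, stride_id=0, valid=True),
                        Stride(start=0.5, end=1.5, stride_id=1, valid=True)])
        out = sg.time_normalize(rec, tl)
        assert [c.stride_id for c in out.cycles] == [0]


def _cycle_set(values_by_level, channels=("m1", "m2")):
    cycles = []
    sid = 0
    for lv, mats in values_by_level.items():
        for mat in mats:
            cycles.append(Cycle(stride_id=sid, data=np.asarray(mat, dtype=float),
                                level=lv))
            sid += 1
    return NormalizedCycleSet(channels=list(channels), cycles=cycles)


class TestScaleToLowSupport:
    def test_constant_low_cycles_become_one(self):
        cs = _cycle_set({"low": [np.full((200, 2), 2.0)]})
        out = sg.scale_to_low_support(cs)
        np.testing.assert_allclose(out.cycles[0].data, 1.0)

    def test_scaling_arithmetic(self):
        low = np.full((200, 2), 0.5)
        no = np.full((200, 2), 1.0)
        cs = _cycle_set({"low": [low], "no": [no]})
        out = sg.scale_to_low_support(cs)
        no_scaled = [c for c in out.cycles if c.level == "no"][0]
        np.testing.assert_allclose(no_scaled.data, 2.0)

    def test_low_level_grand_mean_is_one(self, unit_gains_gt, session_default):
        sess = session_default
        env = sg.envelope(sg.filter_emg(sess.emg))
        tl = sg.select_valid_strides(sess.timeline, sess.interruptions)
        sup = sg.bws_per_stride(sess.force, tl, sg.estimate_body_weight(sess.weighing))
        cyc = sg.scale_to_low_support(
            sg.attach_levels(sg.time_normalize(env, tl), sup.level))
        low = np.stack([c.data for c in cyc.by_level("low")])
        np.testing.assert_allclose(low.mean(axis=(0, 1)), 1.0, atol=1e-12)

    def test_errors_name_the_problem(self):
        with pytest.raises(ValueError, match="low"):
            sg.scale_to_low_support(_cycle_set({"no": [np.ones((200, 2))]}))
        bad = np.ones((200, 2))
        bad[:, 1] = 0.0
        with pytest.raises(ValueError, match="m2"):
            sg.scale_to_low_support(_cycle_set({"low": [bad]}))


class TestGrandAverage:
    def test_single_cycle_average_is_the_cycle(self):
        mat = np.random.default_rng(0).uniform(0, 1, (200, 2))
        out = sg.grand_average(_cycle_set({"no": [mat]}))
        np.testing.assert_array_equal(out["no"].mean, mat)

    def test_mean_and_sem_arithmetic(self):
        out = sg.grand_average(_cycle_set({"no": [np.ones((200, 2)),
                                                  3 * np.ones((200, 2))]}))
        np.testing.assert_allclose(out["no"].mean, 2.0)
        np.testing.assert_allclose(out["no"].sem, 1.0)

    def test_pooled_differs_from_per_subject_with_unequal_strides(self):
        a = Cycle(stride_id=0, data=np.full((200, 1), 1.0), level="no", subject="sA")
        b = Cycle(stride_id=1, data=np.full((200, 1), 1.0), level="no", subject="sA")
        c = Cycle(stride_id=2, data=np.full((200, 1), 4.0), level="no", subject="sB")
        cs = NormalizedCycleSet(channels=["m1"], cycles=[a, b, c])
        pooled = sg.grand_average(cs)["no"].mean[0, 0]
        per_subj = sg.grand_average(cs, per_subject=True)["no"].mean[0, 0]
        assert pooled == pytest.approx(2.0)
        assert per_subj == pytest.approx(2.5)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_preprocess_chain_deterministic_and_nonnegative(seed):
    """Same raw input always yields the same non-negative envelope."""
    rng = np.random.default_rng(seed)
    rec = _rec(rng.standard_normal(3000))
    a = sg.envelope(sg.filter_emg(sg.interpolate_artifacts(rec)))
    b = sg.envelope(sg.filter_emg(sg.interpolate_artifacts(rec)))
    assert np.array_equal(a.data, b.data)
    assert np.all(a.data >= 0)
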