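"""Raw EMG to amplitude-scaled, 200-sample gait-cycle envelopes.

The chain is: spike-artifact interpolation (10 SD / +-150 ms rule), zero-phase
high-pass and mains-notch filtering, analytic-signal envelope with a 5 Hz
low-pass, time normalization of each valid stride to 200 samples, amplitude
scaling to the low-support per-muscle mean, and (per-level) grand averaging.
All filters are applied forward-backward, so the stated orders are the design
orders and the effective magnitude response is squared.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .datatypes import (
    LEVELS,
    Cycle,
    EmgRecording,
    GaitTimeline,
    GrandAverage,
    NormalizedCycleSet,
)

logger = logging.getLogger(__name__)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def interpolate_artifacts(
    rec: EmgRecording, sd_multiple: float = 10.0, half_window: float = 0.150
) -> EmgRecording:
    """Linearly interpolate +-``half_window`` epochs around extreme spikes.

    A sample is a spike when its absolute value exceeds ``sd_multiple`` times
    the channel's standard deviation (computed on the input channel, before
    any replacement). Each flagged sample is replaced together with its
    surrounding epoch by a straight line between the nearest retained samples;
    overlapping epochs are merged. Epochs clipped by the record boundary fall
    back to the nearest retained sample on the surviving side.
    """
    w = int(round(half_window * rec.rate))
    if w < 1:
        raise ValueError("half_window must span at least one sample")
    out = rec.data.copy()
    n = rec.n_samples
    for k in range(out.shape[1]):
        x = rec.data[:, k]
        thr = sd_multiple * x.std()
        hits = np.flatnonzero(np.abs(x) > thr)
        if hits.size == 0:
            continue
        epochs = _merge_intervals([(max(0, i - w), min(n - 1, i + w)) for i in hits])
        y = out[:, k]
        for a, b in epochs:
            left = x[a - 1] if a > 0 else None
            right = x[b + 1] if b < n - 1 else None
            if left is None and right is None:
                continue  # whole record flagged; nothing retained to anchor on
            if left is None:
                y[a:b + 1] = right
            elif right is None:
                y[a:b + 1] = left
            else:
                y[a:b + 1] = np.linspace(left, right, b - a + 3)[1:-1]
    return rec.copy_with(data=out)


def filter_emg(
    rec: EmgRecording, highpass_hz: float = 30.0, notch_hz: float = 50.0,
    notch_q: float = 30.0,
) -> EmgRecording:
    """Zero-phase 2nd-order Butterworth high-pass plus 4th-order mains notch.

    The notch is a cascade of two identical biquad notch sections at
    ``notch_hz`` (default 50 Hz, quality factor ``notch_q``), applied
    forward-backward like the high-pass, so pulse peaks do not shift.
    """
    if notch_hz >= rec.rate / 2:
        raise ValueError("notch_hz must be below the Nyquist frequency")
    sos_hp = signal.butter(2, highpass_hz, btype="highpass", fs=rec.rate, output="sos")
    b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.rate)
    sos_notch = np.vstack([signal.tf2sos(b, a)] * 2)
    out = signal.sosfiltfilt(sos_hp, rec.data, axis=0)
    out = signal.sosfiltfilt(sos_notch, out, axis=0)
    return rec.copy_with(data=out)


def envelope(rec: EmgRecording, lowpass_hz: float = 5.0) -> EmgRecording:
    """Modulus of the analytic signal, low-passed at ``lowpass_hz``.

    The low-pass is a zero-phase 2nd-order Butterworth; its ringing can
    undershoot zero, so the output is clipped at 0 (the factorisation
    downstream requires non-negative input).
    """
    analytic = signal.hilbert(rec.data, axis=0)
    env = np.abs(analytic)
    sos = signal.butter(2, lowpass_hz, btype="lowpass", fs=rec.rate, output="sos")
    env = signal.sosfiltfilt(sos, env, axis=0)
    return rec.copy_with(data=np.clip(env, 0.0, None))


def time_normalize(
    env: EmgRecording, timeline: GaitTimeline, samples: int = 200,
    subject: str = "s1",
) -> NormalizedCycleSet:
    """Resample each valid stride onto ``samples`` evenly spaced points.

    The query grid spans ``[strike, next_strike)``: point ``i`` sits at
    ``strike + i/samples * duration``, so the first point is the strike
    instant itself. Values come from linear interpolation on the original
    time grid. Strides that extend beyond the recording are skipped with a
    warning. Support-level labels are attached later from the force data.
    """
    t = env.times
    cycles: list[Cycle] = []
    valid = timeline.valid_strides()
    if not valid:
        raise ValueError("timeline contains no valid strides")
    for stride in valid:
        q = stride.start + np.arange(samples) / samples * stride.duration
        if q[0] < t[0] or q[-1] > t[-1]:
            logger.warning("stride %d [%0.3f, %0.3f] outside recording; skipped",
                           stride.stride_id, stride.start, stride.end)
            continue
        mat = np.column_stack([np.interp(q, t, env.data[:, k])
                               for k in range(env.data.shape[1])])
        cycles.append(Cycle(stride_id=stride.stride_id, data=mat, subject=subject))
    return NormalizedCycleSet(channels=list(env.channels), cycles=cycles, n_points=samples)


def attach_levels(cycles: NormalizedCycleSet, level_by_stride: dict[int, str]) -> NormalizedCycleSet:
    """Label each cycle with its stride's support level; drops unlabelled
    and excluded (>=95% support) cycles."""
    kept = []
    for c in cycles.cycles:
        lv = level_by_stride.get(c.stride_id)
        if lv in LEVELS:
            kept.append(Cycle(stride_id=c.stride_id, data=c.data, level=lv, subject=c.subject))
    return NormalizedCycleSet(channels=cycles.channels, cycles=kept,
                              n_points=cycles.n_points,
                              scale_reference=cycles.scale_reference)


def scale_to_low_support(cycles: NormalizedCycleSet) -> NormalizedCycleSet:
    """Divide every envelope by the muscle's mean over all low-support cycles.

    After scaling, the per-muscle grand mean over the low-support level is
    exactly 1; the scaling makes amplitudes unitless and comparable across
    sessions.
    """
    low = cycles.by_level("low")
    if not low:
        raise ValueError('no cycles labelled "low" (10-35% support); cannot scale')
    ref = np.stack([c.data for c in low]).mean(axis=(0, 1))  # per-muscle scalar
    zero = np.flatnonzero(ref == 0)
    if zero.size:
        raise ValueError(
            "zero low-support mean for muscle(s): "
            + ", ".join(cycles.channels[i] for i in zero)
        )
    scaled = [Cycle(stride_id=c.stride_id, data=c.data / ref, level=c.level,
                    subject=c.subject) for c in cycles.cycles]
    return NormalizedCycleSet(channels=cycles.channels, cycles=scaled,
                              n_points=cycles.n_points, scale_reference=ref)


def grand_average(
    cycles: NormalizedCycleSet, per_subject: bool = False
) -> dict[str, GrandAverage]:
    """Sample-wise mean envelope per support level, with standard errors.

    Pooled mode (default) averages over all cycles of a level regardless of
    subject; per-subject mode first averages within each subject and then
    averages the subject means (SEM then taken across subjects).
    """
    out: dict[str, GrandAverage] = {}
    for lv in cycles.levels_present():
        group = cycles.by_level(lv)
        if per_subject:
            subjects = sorted({c.subject for c in group})
            stack = np.stack([
                np.stack([c.data for c in group if c.subject == s]).mean(axis=0)
                for s in subjects
            ])
        else:
            stack = np.stack([c.data for c in group])
        n = stack.shape[0]
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(stack[0])
        out[lv] = GrandAverage(mean=stack.mean(axis=0), sem=sem, n=n)
    if not out:
        raise ValueError("no labelled cycles to average")
    return out
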