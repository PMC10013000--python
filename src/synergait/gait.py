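"""Stride segmentation, sequence validity, and body-weight-support levels.

A stride runs from one right foot strike to the next. A sequence of strides
counts only if at least three consecutive strides are present, and the first
and last stride of each sequence are discarded, as are strides overlapping an
annotated interruption (jumps, stops — identified from video in practice,
supplied here as an explicit annotation). Support per stride is the
percentage reduction of the stride-mean filtered vertical force relative to
the body weight measured in the weighing trial, and strides are binned into
no (<10%), low (10-35%), medium (35-55%) and high (55-95%) support.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .datatypes import ForceTrace, GaitTimeline, Stride, SupportAssignment

logger = logging.getLogger(__name__)

MIN_SEQUENCE_STRIDES = 3

#: Upper (exclusive) bound of each support band, in % body weight.
LEVEL_BOUNDS = (("no", 10.0), ("low", 35.0), ("medium", 55.0), ("high", 95.0))


def build_strides(timeline: GaitTimeline) -> GaitTimeline:
    """Derive candidate strides from consecutive right foot strikes."""
    strikes = timeline.right_strikes()
    strides = [Stride(start=float(a), end=float(b), stride_id=i)
               for i, (a, b) in enumerate(zip(strikes[:-1], strikes[1:]))]
    return GaitTimeline(events=timeline.events, strides=strides)


def select_valid_strides(
    timeline: GaitTimeline, interruptions: list[tuple[float, float]] | None = None
) -> GaitTimeline:
    """Apply the sequence-validity rules and mark surviving strides valid.

    Strides overlapping an interruption are removed and split the sequence;
    sequences shorter than three strides are dropped entirely; in every
    surviving sequence the first and last stride are excluded.
    """
    if not timeline.strides:
        timeline = build_strides(timeline)
    interruptions = interruptions or []

    def interrupted(s: Stride) -> bool:
        return any(s.start < b and s.end > a for a, b in interruptions)

    sequences: list[list[Stride]] = []
    current: list[Stride] = []
    prev_end = None
    for s in timeline.strides:
        if s.duration <= 0:
            raise ValueError(f"stride {s.stride_id} has non-positive duration")
        broken = interrupted(s) or (prev_end is not None and s.start != prev_end)
        if broken and current:
            sequences.append(current)
            current = []
        if not interrupted(s):
            current.append(s)
            prev_end = s.end
        else:
            prev_end = None
    if current:
        sequences.append(current)

    out: list[Stride] = []
    for seq_id, seq in enumerate(sequences):
        long_enough = len(seq) >= MIN_SEQUENCE_STRIDES
        for pos, s in enumerate(seq):
            valid = long_enough and 0 < pos < len(seq) - 1
            out.append(Stride(start=s.start, end=s.end, stride_id=s.stride_id,
                              sequence=seq_id, valid=valid))
    return GaitTimeline(events=timeline.events, strides=out)


def filter_force(force: ForceTrace, cutoff_hz: float = 20.0) -> ForceTrace:
    """Zero-phase 12th-order Butterworth low-pass (design order 12)."""
    if cutoff_hz >= force.rate / 2:
        raise ValueError("cutoff_hz must be below the Nyquist frequency")
    sos = signal.butter(12, cutoff_hz, btype="lowpass", fs=force.rate, output="sos")
    return ForceTrace(rate=force.rate, values=signal.sosfiltfilt(sos, force.values),
                      t0=force.t0)


def estimate_body_weight(weighing: ForceTrace, min_duration: float = 2.0) -> float:
    """Body weight in N: mean of the filtered quiet-standing force trial."""
    if weighing.duration < min_duration:
        raise ValueError(
            f"weighing trial lasts {weighing.duration:.2f} s; need >= {min_duration} s"
        )
    return float(filter_force(weighing).values.mean())


def assign_level(bws_percent: float) -> str:
    """Map a support percentage onto its level label.

    Bands are half-open with the boundary owned by the upper level
    (35% is medium); at or above 95% the stride is excluded.
    """
    if bws_percent < 0:
        raise ValueError("bws_percent must be >= 0")
    for label, upper in LEVEL_BOUNDS:
        if bws_percent < upper:
            return label
    return "excluded"


def bws_per_stride(
    force: ForceTrace, timeline: GaitTimeline, body_weight: float
) -> SupportAssignment:
    """Support percentage and level for every valid stride.

    ``bws = 100 * (1 - mean(filtered force over the stride) / body_weight)``,
    clamped at 0 (a stride pressed into the treadmill is "no support").
    Strides reaching outside the force record are excluded with a warning.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    filt = filter_force(force)
    t = filt.times
    bws: dict[int, float] = {}
    level: dict[int, str] = {}
    for s in timeline.valid_strides():
        if s.start < t[0] or s.end > t[-1]:
            logger.warning("stride %d outside force record; excluded", s.stride_id)
            level[s.stride_id] = "excluded"
            bws[s.stride_id] = float("nan")
            continue
        sel = (t >= s.start) & (t < s.end)
        mean_f = filt.values[sel].mean()
        pct = max(0.0, 100.0 * (1.0 - mean_f / body_weight))
        bws[s.stride_id] = pct
        level[s.stride_id] = assign_level(pct)
    return SupportAssignment(body_weight=body_weight, bws_percent=bws, level=level)
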