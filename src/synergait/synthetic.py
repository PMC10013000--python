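"""Synthetic toddler treadmill sessions with known synergy structure.

The generator produces the statistical structure the analysis assumes:
muscle envelopes are a non-negative mixture ``W @ P`` of gait-phase-locked
temporal templates, modulated per support level, riding on a broadband
(10-500 Hz) carrier; vertical force realises a prescribed body-weight-support
percentage per stride. Every downstream stage can therefore be tested
against a known answer without any recording.

Temporal templates are circular Gaussian bumps in normalized cycle phase
(sigma = 10% of the cycle) peaking at evenly spaced phases; for four
synergies these are the right foot strike (0%), right stance (25%), left
foot strike (50%) and left stance (75%) synergies. Spatial weights are
lateralised: right-side muscles dominate the right-phase synergies and
vice versa, with bilateral trunk (erector spinae) contributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .datatypes import (
    LEVELS,
    EmgRecording,
    ForceTrace,
    GaitTimeline,
    default_channel_labels,
)

N_CYCLE_SAMPLES = 200

#: Per-level synergy gains emulating the study conditions for four synergies
#: (first-steps group): foot-strike synergies S1/S3 drop by 17/39/49% and
#: 36/51/62% at low/medium/high support, S2 changes by +13/+6/-2% and S4 by
#: +25/+23/+22%.
STUDY_LEVEL_GAINS: dict[str, tuple[float, ...]] = {
    "no": (1.00, 1.00, 1.00, 1.00),
    "low": (0.83, 1.13, 0.64, 1.25),
    "medium": (0.61, 1.06, 0.49, 1.23),
    "high": (0.51, 0.98, 0.38, 1.22),
}

#: Target support percentage per level, centred in each level's band.
DEFAULT_BWS_TARGETS: dict[str, float] = {"no": 5.0, "low": 22.0, "medium": 45.0, "high": 75.0}


@dataclass
class GroundTruth:
    """Known synergy structure behind a simulated session.

    ``templates`` (n_synergies x 200) have unit maximum; ``patterns`` are the
    gain-scaled per-level versions. ``stride_plan`` rows are
    ``(duration_s, target_bws_percent, level)`` in session order, grouped in
    one sequence per level separated by interruptions.
    """

    weights: np.ndarray
    templates: np.ndarray
    level_gains: dict[str, np.ndarray]
    stride_plan: list[tuple[float, float, str]]
    seed: int
    channels: list[str] = field(default_factory=list)

    @property
    def patterns(self) -> dict[str, np.ndarray]:
        return {lv: self.templates * g[:, None] for lv, g in self.level_gains.items()}

    @property
    def n_synergies(self) -> int:
        return self.weights.shape[1]

    @property
    def n_muscles(self) -> int:
        return self.weights.shape[0]

    def envelopes(self, level: str) -> np.ndarray:
        """Noise-free muscle envelopes (n_muscles x 200) at a support level."""
        return self.weights @ self.patterns[level]


@dataclass
class SyntheticSession:
    """A complete simulated session plus the annotations the pipeline reads."""

    emg: EmgRecording
    timeline: GaitTimeline
    force: ForceTrace
    weighing: ForceTrace
    interruptions: list[tuple[float, float]]
    body_weight: float

    def __iter__(self):
        # Allows ``emg, timeline, force, weighing = simulate_session(...)``.
        return iter((self.emg, self.timeline, self.force, self.weighing))


def _circular_gaussian_bump(peak: int, sigma: float, n: int = N_CYCLE_SAMPLES) -> np.ndarray:
    idx = np.arange(n)
    d = np.minimum(np.abs(idx - peak), n - np.abs(idx - peak))
    return np.exp(-0.5 * (d / sigma) ** 2)


def make_ground_truth(
    n_synergies: int = 4,
    n_muscles: int = 24,
    level_gains: dict[str, "np.ndarray | tuple[float, ...] | list[float]"] | None = None,
    seed: int = 0,
    *,
    strides_per_level: int = 10,
    bws_targets: dict[str, float] | None = None,
    cadence: float = 75.0,
    sigma_fraction: float = 0.10,
) -> GroundTruth:
    """Draw a seeded ground-truth synergy structure and stride plan.

    Parameters
    ----------
    n_synergies : int
        Number of synergies (templates peak at phases ``i / n_synergies``).
    n_muscles : int
        Even number of bilateral channels.
    level_gains : mapping level -> per-synergy gain, optional
        Amplitude multiplier applied to each template at each support level.
        Defaults to all ones; :data:`STUDY_LEVEL_GAINS` reproduces the study
        conditions for ``n_synergies=4``.
    seed : int
        Seeds weights, stride durations — the full ground truth.
    strides_per_level : int
        Strides simulated per support level (one sequence per level; the
        first and last of each sequence are later trimmed by the stride
        selection rule).
    cadence : float
        Strides per minute; stride durations are drawn from a normal
        distribution around ``60 / cadence`` truncated at +-20%.
    """
    if n_synergies < 1:
        raise ValueError("n_synergies must be >= 1")
    if n_muscles % 2:
        raise ValueError("n_muscles must be even (bilateral pairs)")
    if cadence <= 0:
        raise ValueError("cadence must be positive")

    if level_gains is None:
        level_gains = {lv: np.ones(n_synergies) for lv in LEVELS}
    gains = {lv: np.asarray(g, dtype=float) for lv, g in level_gains.items()}
    for lv, g in gains.items():
        if g.shape != (n_synergies,):
            raise ValueError(f"level_gains[{lv!r}] must have length {n_synergies}")
        if np.any(g <= 0):
            raise ValueError(f"level_gains[{lv!r}] must be strictly positive")
    bws = dict(DEFAULT_BWS_TARGETS if bws_targets is None else bws_targets)
    for lv, b in bws.items():
        if not 0 <= b < 95:
            raise ValueError(f"target BWS for level {lv!r} must lie in [0, 95)")

    rng = np.random.default_rng(seed)
    sigma = sigma_fraction * N_CYCLE_SAMPLES

    peaks = [round(i * N_CYCLE_SAMPLES / n_synergies) for i in range(n_synergies)]
    templates = np.array([_circular_gaussian_bump(p, sigma) for p in peaks])

    half = n_muscles // 2
    weights = rng.uniform(0.0, 0.05, size=(n_muscles, n_synergies))  # co-activation floor
    # Synergies peaking in the first half of the cycle are right-side events
    # (right strike/stance), the rest left-side; within a side each synergy
    # recruits a distinct functional muscle group (e.g. dorsiflexors and
    # hamstrings at foot strike vs plantarflexors, quadriceps and gluteals
    # in stance), which is what makes the synergies spatially separable.
    for side, offset in (("right", 0), ("left", half)):
        syns = [i for i, p in enumerate(peaks)
                if (p < N_CYCLE_SAMPLES / 2) == (side == "right")]
        if not syns:
            continue
        side_muscles = list(range(offset, offset + half))
        if half == 12 and len(syns) == 2:
            # canonical bilateral set: strike group = TA, RF, BF, SEM, TFL;
            # stance group = GM, GL, SOL, VM, VL, GLM
            groups = [[offset + j for j in (0, 4, 7, 8, 9)],
                      [offset + j for j in (1, 2, 3, 5, 6, 10)]]
        else:
            groups = [side_muscles[g::len(syns)] for g in range(len(syns))]
        for grp, i in zip(groups, syns):
            weights[grp, i] += rng.uniform(0.55, 0.95, size=len(grp))
    # bilateral trunk contribution on the last channel of each side (ES)
    for es in (half - 1, n_muscles - 1):
        weights[es, :] = rng.uniform(0.10, 0.25, size=n_synergies)
    if np.linalg.matrix_rank(weights) < n_synergies:  # pragma: no cover
        raise RuntimeError("degenerate weight draw: weight matrix not full column rank")

    mean_dur = 60.0 / cadence
    plan: list[tuple[float, float, str]] = []
    for lv in LEVELS:
        if lv not in gains:
            continue
        durs = rng.normal(mean_dur, 0.08 * mean_dur, size=strides_per_level)
        durs = np.clip(durs, 0.8 * mean_dur, 1.2 * mean_dur)
        plan.extend((float(d), float(bws[lv]), lv) for d in durs)

    return GroundTruth(
        weights=weights,
        templates=templates,
        level_gains=gains,
        stride_plan=plan,
        seed=seed,
        channels=default_channel_labels(n_muscles),
    )


def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float,
                       band: tuple[float, float] = (10.0, 500.0)) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to the acquisition band."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def simulate_session(
    gt: GroundTruth,
    cadence: float | None = None,
    stance_fraction: float = 0.6,
    body_weight: float = 100.0,
    artifact_rate: float = 2.0,
    seed: int = 0,
    *,
    emg_rate: float = 2000.0,
    force_rate: float = 1000.0,
    env_snr: float = 10.0,
    gap_s: float = 2.0,
) -> SyntheticSession:
    """Render a ground truth into raw-like EMG, events, force and weighing data.

    Per muscle, the raw EMG is the ground-truth envelope (warped to each
    stride's duration) multiplied by a zero-mean 10-500 Hz Gaussian carrier,
    plus a carrier-shaped noise floor sized so that the envelope-domain SNR
    is ``env_snr``. Optional single-sample spike artifacts of 20 channel
    standard deviations are injected at ``artifact_rate`` expected events per
    channel. The vertical force realises each stride's planned support
    percentage in its stride mean; the weighing trial fluctuates about
    ``body_weight``.
    """
    if stance_fraction <= 0 or stance_fraction >= 1:
        raise ValueError("stance_fraction must lie in (0, 1)")
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    if artifact_rate < 0:
        raise ValueError("artifact_rate must be non-negative")
    if cadence is not None and cadence <= 0:
        raise ValueError("cadence must be positive")

    rng = np.random.default_rng(seed)
    durations = np.array([d for d, _, _ in gt.stride_plan])
    if cadence is not None:
        durations = durations * (60.0 / cadence) / durations.mean()
    levels = [lv for _, _, lv in gt.stride_plan]
    bws_targets = np.array([b for _, b, _ in gt.stride_plan])

    # --- stride start times: one sequence per contiguous level block, gaps between
    starts = np.empty(len(durations))
    seq_bounds: list[tuple[int, int]] = []
    t = gap_s
    seq_start = 0
    for j, dur in enumerate(durations):
        if j > 0 and levels[j] != levels[j - 1]:
            seq_bounds.append((seq_start, j))
            seq_start = j
            t += gap_s
        starts[j] = t
        t += dur
    seq_bounds.append((seq_start, len(durations)))
    total_t = t + gap_s

    # --- events
    events: list[tuple[float, str, str]] = []
    for a, b in seq_bounds:
        for j in range(a, b):
            s, d = starts[j], durations[j]
            events.append((s, "right", "strike"))
            events.append((s + stance_fraction * d, "right", "off"))
            events.append((s + 0.5 * d, "left", "strike"))
            events.append((min(s + (0.5 + stance_fraction) * d, s + 0.999 * d), "left", "off"))
        events.append((starts[b - 1] + durations[b - 1], "right", "strike"))
    events.sort()
    timeline = GaitTimeline(events=events)

    interruptions = [(0.0, starts[0] - 0.05)]
    for (_, b0), (a1, _) in zip(seq_bounds[:-1], seq_bounds[1:]):
        interruptions.append((starts[b0 - 1] + durations[b0 - 1] + 0.05, starts[a1] - 0.05))
    interruptions.append((total_t - gap_s + 0.05, total_t))

    # --- EMG: envelope track per muscle, continuous carrier, noise floor
    n_emg = int(round(total_t * emg_rate))
    m = gt.n_muscles
    patterns = gt.patterns
    # Between-sequence gaps are not silent: the child is held, braced and
    # repositioned, so muscles stay tonically active at burst-like amplitude.
    # These segments are excluded from analysis via the interruption
    # annotations, but they keep each channel's overall standard deviation
    # representative, as in real recordings.
    peak_env = (gt.weights @ patterns["no" if "no" in patterns else levels[0]]).max(axis=1)
    t_grid = np.arange(n_emg) / emg_rate
    gap_phase = rng.uniform(0, 2 * np.pi, size=m)
    env = 0.7 * peak_env * (0.85 + 0.15 * np.sin(
        2 * np.pi * 0.8 * t_grid[:, None] + gap_phase))
    phase_grid = np.arange(N_CYCLE_SAMPLES)
    stride_mask = np.zeros(n_emg, dtype=bool)
    for j, (s, d) in enumerate(zip(starts, durations)):
        i0, i1 = int(round(s * emg_rate)), int(round((s + d) * emg_rate))
        mix = gt.weights @ patterns[levels[j]]  # m x 200
        phase = np.arange(i1 - i0) / (i1 - i0) * N_CYCLE_SAMPLES
        # periodic interpolation of the cycle-locked envelope
        warped = np.empty((i1 - i0, m))
        for k in range(m):
            warped[:, k] = np.interp(phase, np.append(phase_grid, N_CYCLE_SAMPLES),
                                     np.append(mix[k], mix[k, 0]))
        env[i0:i1] = warped
        stride_mask[i0:i1] = True

    raw = np.empty_like(env)
    for k in range(m):
        carrier = _bandlimited_noise(rng, n_emg, emg_rate)
        noise = _bandlimited_noise(rng, n_emg, emg_rate)
        # SNR is defined against the locomotor (within-stride) envelope
        noise_sigma = math.sqrt(np.mean(env[stride_mask, k] ** 2)) / env_snr
        raw[:, k] = env[:, k] * carrier + noise_sigma * noise

    if artifact_rate > 0:
        for k in range(m):
            n_art = rng.poisson(artifact_rate)
            if n_art:
                idx = rng.integers(0, n_emg, size=n_art)
                raw[idx, k] = 20.0 * raw[:, k].std() * rng.choice([-1.0, 1.0], size=n_art)

    emg = EmgRecording(channels=list(gt.channels), rate=emg_rate, data=raw)

    # --- force: stride means realise the planned support, gaps at body weight
    n_f = int(round(total_t * force_rate))
    force = np.full(n_f, body_weight)
    for j, (s, d) in enumerate(zip(starts, durations)):
        i0, i1 = int(round(s * force_rate)), int(round((s + d) * force_rate))
        mean_f = (1.0 - bws_targets[j] / 100.0) * body_weight
        phase = np.arange(i1 - i0) / (i1 - i0)
        wobble = 0.05 * body_weight * np.sin(2 * np.pi * phase + rng.uniform(0, 2 * np.pi))
        wobble -= wobble.mean()  # keep the stride mean exact
        force[i0:i1] = mean_f + wobble
    force = force + 0.005 * body_weight * rng.standard_normal(n_f)
    force_trace = ForceTrace(rate=force_rate, values=force)

    n_w = int(round(3.0 * force_rate))
    tw = np.arange(n_w) / force_rate
    weigh = (body_weight
             + 0.02 * body_weight * np.sin(2 * np.pi * 2.0 * tw)
             + 0.005 * body_weight * rng.standard_normal(n_w))
    weighing = ForceTrace(rate=force_rate, values=weigh)

    return SyntheticSession(
        emg=emg,
        timeline=timeline,
        force=force_trace,
        weighing=weighing,
        interruptions=interruptions,
        body_weight=body_weight,
    )
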