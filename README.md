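# synergait

Muscle synergy and muscle network analysis for body-weight-supported
locomotion, built for multi-channel surface EMG of toddler treadmill walking.

When young children walk with part of their body weight carried by an
experimenter, the structure of their motor output changes. This package
implements the full analysis chain used to quantify that change:

1. **EMG preprocessing** — spike-artifact interpolation (±150 ms around
   samples exceeding 10× the channel SD), zero-phase 30 Hz high-pass and
   mains-notch filtering, envelope extraction as the modulus of the analytic
   signal with a 5 Hz low-pass.
2. **Gait and body-weight support (BWS)** — strides from right foot strike
   to the next right foot strike; sequences of < 3 strides and the first/last
   stride of each sequence discarded; per-stride support computed as
   `BWS = 100·(1 − mean vertical force / body weight)` from 20 Hz low-passed
   force, and binned into no (<10%), low (10–35%), medium (35–55%) and high
   (55–95%) support.
3. **Muscle synergies** — envelopes are time-normalized to `s = 200` samples
   per gait cycle, amplitude-scaled to the low-support per-muscle mean,
   grand-averaged per level, and the `k = 4` level averages are stacked into
   an `(s·k) × m` matrix (800 × 24 for the full muscle set). Non-negative
   matrix factorisation by multiplicative updates decomposes it as

   `EMG ≈ P · Wᵀ`

   with temporal patterns `P` per support level and weighting coefficients
   `W` (m × n) shared across levels. The number of synergies is the smallest
   `n ∈ 1..7` whose reconstruction quality

   `λ(n) = (1 − ‖EMG − W P‖²_F / ‖EMG‖²_F) · 100%`

   reaches 88% within every level's block. Per synergy, the pipeline reports
   the mean temporal-pattern amplitude per level relative to no support,
   peak-normalized patterns, and circular cross-correlations between levels.
4. **Muscle networks** — weighting coefficients scaled by the summed
   integrals of the temporal patterns, squared into a muscle × muscle
   connectivity matrix via the outer product, thresholded at 5·10⁻⁵; density
   and weighted transitivity summarize each synergy's network topology.

Because recordings of this kind are not publicly distributable, the package
ships a first-class synthetic-data module: sessions with known ground-truth
synergies, gait-phase-locked Gaussian activation bumps, per-level amplitude
gains, broadband (10–500 Hz) EMG carriers, spike artifacts, and force traces
realising a prescribed support percentage per stride. Every pipeline stage is
validated by recovering that known structure.

## Worked example

Simulate a two-session study whose per-level synergy gains follow the
published modulations (foot-strike synergies S1/S3 dropping by −17/−39/−49%
and −36/−51/−62% at low/medium/high support), then run the pipeline:

```bash
$ synergait simulate --out study --sessions 2 --seed 3
wrote 2 session(s) and ground truth under study

$ synergait run --config study/study.yaml --out results
selected 4 synergies (lambda overall 99.9%); results under results

$ synergait metrics --results results
mean amplitude change vs no support [no]: S1: +0.0%, S2: +0.0%, S3: +0.0%, S4: +0.0%
mean amplitude change vs no support [low]: S1: -14.0%, S2: +11.2%, S3: -35.3%, S4: +23.9%
mean amplitude change vs no support [medium]: S1: -36.8%, S2: +7.7%, S3: -50.4%, S4: +26.3%
mean amplitude change vs no support [high]: S1: -46.0%, S2: -0.5%, S3: -60.7%, S4: +27.2%
```

Four synergies are required, ordered by their no-support peak time:
S1/S3 peak at the right/left foot strike and lose amplitude as support
increases, recovering the generator's planned modulations to within a few
percentage points, while the stance-phase synergies S2/S4 stay flat or grow
— the signature pattern of body-weight unloading. `results/` also contains
the 24 × 4 weighting matrix, the four 200 × 4 temporal-pattern blocks, the
per-level λ table, circular cross-correlations, and per-synergy network
edge lists and metrics, all as tab-separated text stamped with the config
hash that produced them.

The same analysis is available as a library:

```python
import synergait as sg

gt = sg.make_ground_truth(level_gains=sg.STUDY_LEVEL_GAINS, seed=3)
sess = sg.simulate_session(gt, seed=30)
env = sg.envelope(sg.filter_emg(sg.interpolate_artifacts(sess.emg)))
timeline = sg.select_valid_strides(sess.timeline, sess.interruptions)
support = sg.bws_per_stride(sess.force, timeline,
                            sg.estimate_body_weight(sess.weighing))
cycles = sg.scale_to_low_support(
    sg.attach_levels(sg.time_normalize(env, timeline), support.level))
X, index = sg.concatenate_levels(sg.grand_average(cycles))
model = sg.order_synergies(sg.select_n(X, index, seed=0))
print(model.n, model.lambda_by_level)
```

The factorisation core is a scikit-learn-style estimator
(`sg.MuscleSynergyNMF(n_components=4).fit(X)`) with `weights_`, `patterns_`
and `reconstruction_quality_` fitted attributes.

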