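# Methods

This note documents the models, numerical choices and limitations behind
`synergait`. It describes what the code computes; every number quoted here is
produced by the test suite or by `scripts/acceptance.py`.

## Signal model

A session consists of multi-channel surface EMG (2 kHz), foot-strike /
foot-off events per side, a vertical ground-reaction-force trace (1 kHz) and
a quiet-standing weighing trial (≥ 2 s). The analysis assumes the EMG
envelope of muscle *m* during walking is a non-negative mixture

    e_m(t) = Σ_i  W[m, i] · g_i(level) · p_i(φ(t))

of `n` synergy templates `p_i` locked to gait phase φ, with spatial weights
`W` shared across body-weight-support levels and per-level amplitude gains
`g_i`. The pipeline estimates `W`, the per-level patterns `P_level = g·p`,
and the number `n`.

## Preprocessing

* **Artifact interpolation.** Samples whose absolute value exceeds
  `sd_multiple` (default 10) times the channel's standard deviation are
  replaced, together with ±`half_window` (default 150 ms) around them, by a
  straight line between the nearest retained samples; overlapping epochs are
  merged, and epochs clipped at a record boundary fall back to the nearest
  retained sample on the surviving side. The SD is computed on the raw input
  channel before any replacement — the most direct reading of "the signal's
  standard deviation"; whether the original protocol computed it before or
  after high-pass filtering is not documented, so this choice is recorded
  here as an open convention.
* **Filtering.** 2nd-order Butterworth high-pass at 30 Hz plus a 4th-order
  notch (two cascaded biquads, default 50 Hz — Dutch mains — with quality
  factor Q = 30; both frequency and Q are configurable since the original
  protocol states only the order). "Bi-directional" is implemented as
  forward–backward application (`sosfiltfilt`): zero phase, with the
  magnitude response applied twice. A symmetric test pulse keeps its peak
  sample exactly.
* **Envelope.** Modulus of the analytic signal (Hilbert transform), then a
  zero-phase 2nd-order Butterworth low-pass at 5 Hz. The low-pass can ring
  below zero; output is clipped at 0 because the factorisation requires
  non-negative input.
* **Time normalization.** Each valid stride (right strike to next right
  strike) is resampled to 200 points by linear interpolation on the original
  time grid; point *i* sits at `strike + i/200 · duration`, so sample 0 is
  the strike instant and the grid spans `[strike, next_strike)`. Linear
  interpolation is the least-assuming choice; no resampling method is named
  in the protocol.
* **Amplitude scaling.** Every envelope is divided by that muscle's mean
  over all low-support (10–35%) cycles, making the low-support per-muscle
  grand mean exactly 1. Scaling is applied **per session (per subject)**
  before cycles are pooled across sessions: a per-subject reference is the
  reading that makes cross-subject pooling meaningful, since absolute EMG
  amplitudes are not comparable between electrode placements.

## Support stratification

Strides overlapping an annotated interruption are removed and split their
sequence; sequences with fewer than three strides are dropped; the first and
last stride of every surviving sequence are excluded. Interruptions are an
explicit annotation file (in the original protocol they are identified from
video), not auto-detected. Vertical force is low-passed with a zero-phase
12th-order Butterworth at 20 Hz; body weight is the mean of the filtered
weighing trial; per-stride support is `100·(1 − mean force / body weight)`,
clamped at 0 (downward pressing is treated as "no support"). Support bands
are half-open with the boundary owned by the upper level (35.0% → medium),
and strides at ≥ 95% support are excluded — the protocol's ranges abut, so a
convention was required.

## Synergy extraction

The four per-level grand averages (200 × m each) are stacked no → low →
medium → high into an (800 × m) matrix and factorised by Lee–Seung
multiplicative updates minimising the squared Frobenius error, giving
temporal patterns per level with weights shared across levels. Numerical
choices:

* **Restarts / iterations / tolerance.** 20 random non-negative
  initialisations, up to 2000 iterations each, stopping when the relative
  objective decrease per iteration falls below 1e-8; the restart with the
  lowest objective wins. The original work names only the algorithm family,
  so these are engineering defaults: loose enough to finish quickly, tight
  enough that the objective curve is flat at stopping. The objective is
  evaluated each iteration via the Gram identity
  `‖X−HWᵀ‖² = ‖X‖² − 2⟨XᵀH, W⟩ + ⟨HᵀH, WᵀW⟩`, whose terms are byproducts of
  the updates. Multiplicative updates never increase the objective and never
  produce a negative entry (both property-tested).
* **Scale gauge.** Each weight column is normalised to unit maximum with the
  compensating rescale applied to the patterns; the reconstruction is
  bit-identical under this relabelling, and weights become comparable across
  fits.
* **Model order.** `select_n` fits n = 1…7 in ascending order and returns
  the smallest n with λ ≥ 88% in every level's 200-row block (the criterion
  is evaluated as ≥, with the boundary case noted in the output; whether the
  original "exceed 88%" meant strict inequality at exactly 88.0 is
  undocumented). If no n qualifies, the n = 7 model is returned flagged
  `criterion_met=False`. For each n ≥ 2 one extra restart is warm-started
  from the best (n−1) solution padded with a near-zero column: since the
  updates are monotone, this guarantees best-of-restarts λ(n) is
  non-decreasing in n (up to float rounding) — an algorithmic property, not
  a tuning device.
* **Ordering.** Synergies are sorted by the argmax of their no-support
  pattern (ties: larger weight-column norm first), yielding the conventional
  right-strike / right-stance / left-strike / left-stance order. A synergy
  peaking exactly at the cycle boundary can land at sample 199 instead of 0
  under noise and then sorts last; the ordering contract is kept simple
  (plain argmax) and recovery analyses match synergies by weight similarity
  instead of by rank.
* **Metrics.** Mean-amplitude change of synergy i at a level is
  `100·(mean P_level,i − mean P_no,i)/mean P_no,i`; patterns are also
  normalised to unit maximum over the cycle; similarity between levels is
  the circular cross-correlation — the maximum over all 200 circular lags of
  the Pearson correlation (computed by FFT, verified against a brute-force
  shift loop), with the smallest non-negative lag reported on ties. The
  max-over-lags, mean-removed form is bounded by 1 and robust to small phase
  shifts; the source protocol cites but does not define its estimator.
* **Matching for recovery studies.** Estimated synergies are paired to
  ground-truth synergies greedily by maximum cosine similarity of weight
  columns — deterministic and standard.

## Muscle networks

Weight columns are divided by the sum over levels of the temporal-pattern
integrals (integral over the normalized cycle, so a constant pattern of 1
contributes 1 per level); the scale gauge is re-imposed first so the result
depends only on the product `W Pᵀ`. The outer product of each scaled column
with itself gives a muscle × muscle connectivity matrix; the diagonal
(self-connections) is zeroed and entries below the absolute threshold 5·10⁻⁵
are removed. Two summaries per synergy:

* **Density** — surviving undirected edges divided by `N(N−1)/2`.
* **Transitivity** — weighted: the sum over node triples of the geometric
  mean of the three edge weights of closed triangles
  (`trace((A∘⅓)³)`), divided by the number of connected triples
  (`Σ_i k_i(k_i−1)` with binary degrees k), and 0 when no connected triples
  exist. The weighted variant is used because the quantity is meant to carry
  the edge-weight scale (reported values in this literature are of order
  10⁻⁵, impossible for the binary metric bounded by 1); the exact formula
  used by the original study is not published, so this geometric-mean form —
  the standard weighted-network convention — is an explicit design choice.

## Synthetic data generator

The generator is the package's study stand-in; its defaults define the
conditions every recovery test runs under.

* **Templates.** Circular Gaussian bumps in normalized phase, σ = 10% of the
  cycle, peaking at phases i/n (0, 25, 50, 75% for n = 4), unit maximum.
  The functional form is a modelling choice; only the phase-locked,
  non-negative, foot-strike/stance character is constrained by the domain.
* **Weights.** Each synergy recruits a functionally distinct muscle group —
  per side, a strike group (TA, RF, BF, SEM, TFL) and a stance group
  (GM, GL, SOL, VM, VL, GLM) — with dominant contributions U(0.55, 0.95), a
  co-activation floor U(0, 0.05) everywhere, and bilateral erector-spinae
  contributions U(0.10, 0.25). Published toddler synergy weightings are
  sparse and phase-specific; an earlier draft that boosted whole body sides
  uniformly produced spatially indistinguishable strike/stance synergies
  (weight-column cosines ≈ 0.98) and hence effectively rank-2 mixtures,
  contradicting the four-synergy structure the generator is meant to embody.
* **Gains.** `STUDY_LEVEL_GAINS` encodes the published per-level amplitude
  modulations for four synergies (S1 −17/−39/−49%, S2 +13/+6/−2%,
  S3 −36/−51/−62%, S4 +25/+23/+22% at low/medium/high support); unit gains
  are the neutral default of `make_ground_truth`.
* **Session layout.** One sequence per support level (default 10 strides,
  of which 8 survive the first/last-trim), targets 5/22/45/75% support,
  cadence 75 strides/min with stride durations drawn from a truncated normal
  (±20%), stance fraction 0.6, body weight 100 N (a ~10 kg toddler). These
  sizes keep a full study under a few seconds to simulate and analyse while
  leaving enough cycles for stable averages.
* **EMG synthesis.** Per muscle, the mixture envelope is warped to each
  stride's duration and multiplied by a continuous unit-variance Gaussian
  carrier band-passed to 10–500 Hz (one carrier per muscle for the whole
  session rather than per stride: per-stride regeneration would insert
  filter edge transients exactly at stride boundaries). A second,
  carrier-shaped noise floor is added with amplitude `rms(envelope)/SNR`
  (envelope SNR default 10). Between-sequence gaps contain tonic
  non-locomotor activity at ~0.7× burst amplitude — a held, bracing child
  is not electrically silent — which keeps each channel's overall SD
  representative; without it, genuine burst peaks cross the 10·SD artifact
  threshold and the artifact interpolation wipes the strongest strides.
  Gaps are excluded from analysis through the interruption annotations.
* **Artifacts.** Single-sample spikes of 20× the channel SD, Poisson count
  per channel (default expectation 2 per session), random sign and time —
  unambiguously above the 10·SD detection rule.
* **Force.** Stride means realise the planned support exactly (a zero-mean
  sinusoidal within-stride wobble plus 0.5% white noise); gaps sit at body
  weight; the weighing trial is 3 s of force fluctuating about body weight.
  The true within-stride force shape under manual support is unknown; this
  smooth modulation is a stand-in, not a claim.

**What the generator does not emulate:** electrode crosstalk, stride-to-
stride variability of the synergy patterns themselves (only the carrier and
artifacts vary), non-stationary baselines, movement-artifact spectra
overlapping the signal band, and biomechanically realistic force waveforms.
Consequently, passing recovery tests show the pipeline is correct and
well-conditioned under the assumed signal model — not that real toddler EMG
satisfies that model.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded explicitly;
generator and factorisation seeds are separate config entries. Identical
configuration yields bit-identical output files (asserted down to file
bytes); every output file carries the SHA-256 hash of the configuration that
produced it, and the run manifest records settings, seeds and library
versions.

## Known limitations

* Reference values from the original toddler cohort cannot be reproduced
  because those recordings are available only on request; all quantitative
  validation is recovery-based on synthetic data.
* With support levels near a band boundary (±1 percentage point), measured
  support can fall on either side; the generator's default targets sit well
  inside the bands.
* The multiplicative-update NMF converges linearly; near-degenerate optima
  at large n stop on the iteration cap with a logged, non-fatal warning in
  `fit_meta`.
* The per-subject averaging variant (subject means before pooling) is
  implemented and tested, but per-subject result figures are out of scope.
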