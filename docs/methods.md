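# Methods

This note documents the models and procedures implemented in `tonepred`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Stimulus model

Tone sequences are realizations of a stationary Gaussian process whose
temporal power spectrum follows P(f) ∝ 1/f^β, β ∈ {0.5, 0.99, 1.5}.
Synthesis uses circulant embedding: the spectrum is defined on a discrete
frequency lattice of length M = 4096 (for 33-element series), complex
Gaussian coefficients with that variance profile are inverse-transformed,
and the real part is kept. Because the lattice spectrum is symmetric, the
real and imaginary parts are independent with identical covariance, and
both are used. The 1/f divergence at DC is handled by setting the
zero-frequency power equal to the lowest nonzero-frequency power; with the
spectrum defined directly on the circulant lattice all eigenvalues are
nonnegative, so no clipping is ever needed. The process autocovariance
r(k) used everywhere downstream is the inverse FFT of this lattice
spectrum (normalized to r(0) = 1), which makes synthesis and prediction
exactly consistent.

Each 33-element series is min–max mapped onto [log 220, log 880] Hz and
snapped to a 25-value semitone grid (220·2^(j/12), j = 0..24); values
exactly midway between grid points snap to the lower pitch, a deterministic
and testable convention. The per-sequence min–max reading of "scaled to
range from log(220) to log(880)" was chosen over a global variance
normalization because it guarantees every sequence spans the grid.

### Optimal final-pitch prediction (p34*)

p34* is the conditional mean of element 34 of the zero-mean process given
elements 1–33 — the best linear predictor under the synthesis
autocovariance:

    log p34* = x̄ + aᵀ(x − x̄),   Σ a = c,

with Σ the 33×33 Toeplitz autocovariance, c_j = r(34 − j), and x the
mean-centered log pitches. Solved by Levinson recursion
(`scipy.linalg.solve_toeplitz`), with a ridge fallback for singular inputs.
By default the predictor sees the discretized pitches (what a listener
hears); a switch to the raw scaled series exists. The continuous p34* is
reported alongside its nearest-grid snap; the design bins (low [370, 392],
medium [440], high [494, 523] Hz) are defined on the snap.

Templates are found by rejection sampling per (β, bin) design cell: a
candidate is kept when its penultimate pitch lands on 440 Hz and its
snapped p34* falls in the target bin (budget 10⁶ candidates per cell,
batched synthesis; in practice ~10⁵ candidates fill the rarest cell). The
full design crosses 9 templates × 3 tone durations (150/300/600 ms) × 12
blocks = 324 trials; the six presented final pitches (±4, 8, 12 semitones
around 440 Hz) are balanced, two appearances per distinct sequence.

## Synthetic sessions

The generator emulates a sensor-array (MEG-like) study on a planar grid
(default 12×12; analyses in the test-suite and acceptance run use 8×8 and
6×6 instances to stay desk-scale) split into four contiguous role patches.
Per tone epoch the noiseless activity is:

- **sensory** — a·E(t)·(dc + z(p_i)), with E a Gaussian evoked kernel
  peaking 100 ms post onset (σ = 25 ms) and z standardized log pitch. The
  pitch-independent dc term (default 1) makes the channel a meaningful
  auditory-evoked (M100) localizer; a purely pitch-weighted response would
  have only an accidental nonzero trial-average.
- **informational** — b·Σ_{k=0}^{K−1} λ^k z(p_{i−k}) + c·ẑ₃₄(1..i), where
  ẑ₃₄(1..i) is the running best linear prediction of the final pitch from
  tones 1..i, held constant within the epoch. The predictive term is a slow
  non-baselined build-up, so the tone-33 prediction effect survives window
  averaging without baseline correction. K is fixed in tone count
  (default 7), λ = 0.7.
- **temporal** — the same weighted history sum with
  K = round(T_int / tone duration), T_int = 1200 ms (8/4/2 tones at
  150/300/600 ms).
- **noise** — 0.

Additive noise: white Gaussian per sample (SD 2.5) plus a slow stationary
Ornstein–Uhlenbeck drift (stationary SD 0.3, time constant 2 s, knots
every 0.5 s, linearly interpolated). These defaults put the single-sample
evoked SNR near 0.4 and the 50-ms-window history-signal SNR near 2 — a
deliberately clean but MEG-plausible regime. Stationarity of the drift
matters: demeaned/detrended recordings have bounded slow fluctuations,
and a non-stationary (random-walk) drift would make regression-row noise
grow with trial length, attenuating k′ more in the slow condition and
imprinting a spurious duration tilt on duration-invariant sensors. The
drift is also kept small relative to the white noise for the same reason.
Sampling rate is 300 Hz (all analyses use ≥50 ms windows).

Behavior: likelihood rating = clamp(round(5 − γ·s·|z(p34) − ẑ₃₄(K_subj)| +
ε), 1, 5), where ẑ₃₄(K_subj) is the subject's internal prediction from the
last K_subj tones only, s = 1.5 scales z-units to rating units, and ε has
SD 0.5. With γ = 0 ratings are stimulus-independent. The multi-subject
"coupled" configuration draws K_subj ∈ {4..10} per subject, ties the
informational sensors' K to it, and sets γ = 4/K_subj — planting the
negative across-subject association between neural integration length and
the behavioral interaction effect.

What the generator does **not** emulate: realistic MEG noise covariance and
artifacts, dipolar field topographies (all gains are positive scalars),
source geometry, and between-subject anatomical variability. Two
consequences matter for interpreting tests. First, the early-sensory
channel is genuinely pitch-coupled, so a sufficiently powered low- vs
high-p34* contrast through the M100 filter detects real (weak) differences;
the suite therefore asserts the discriminative property (divergence
concentrated in the predictive channel) rather than an absolute null.
Second, all subjects share one truth in the fixed configuration, so
across-subject variability is purely noise-driven.

## Integration-order estimation (k′)

Raw (non-baseline-corrected) activity is averaged in nonoverlapping 50-ms
windows of every tone. For tones 16–32, activity per sensor and window is
regressed on the current and k′ previous log pitches (k′ = 0..15, 16
models; predictors always exist at these indices, asserted). Model
selection is six-fold cross-validated: folds are balanced with exactly two
repetitions of each of the nine unique sequences (18 trials per fold); all
models are fit on the training folds and scored by test-fold SSE; the
per-fold winner is the arg-min, with ties — at a tolerance scaled to the
test-fold energy, so exactly-fitting models tie — resolved to the smallest
k′; the final k′ is the across-fold mean. Near-singular normal equations
fall back to a minimum-norm solve with a warning. Pitch enters as log
pitch (grid geometry); a linear-Hz switch exists.

The shuffled null permutes tone order 1–32 within each unique sequence in
the training folds only, keeping each design row's current-tone pitch and
leaving test folds untouched. Shuffles are seeded per (sequence, repetition,
fold), hence identical across the 12 repetitions of a sequence and across
tone-duration conditions. 100 repetitions × 6 folds give 600 winners per
cell, fold-averaged to 100 null values. Group inference draws 1000
across-subject means of per-subject random repetitions; p is the proportion
of null means ≥ the observed group mean (one-tailed).

Implementation: all 16 nested models over all sensor/window cells are
scored from per-sequence Gram matrices (the response enters only through
per-sequence fold sums), so a full 100-repetition null costs ~2 s per
subject and condition.

### Known estimator bias

The per-fold arg-min of cross-validated SSE is not a consistent order
estimator: for models above the true order, the expected test-SSE penalty
of one extra parameter (≈ σ²·n_test/n_train) is smaller than the standard
deviation of the test-SSE difference (≈ 0.9 σ²), and both are independent
of the noise level and the trial count. Overfitting models therefore win
folds with substantial probability at any SNR, and the fold-averaged k′
has an upward excess: measured on this design, a pure-noise sensor yields
k′ ≈ 4.5–6 (the "noise floor"), and planted orders are recovered as
true + excess, the excess shrinking as the true order grows. The estimator
consequently cannot report k′ ≈ 1 for a true two-tone integrator — the
value is bounded below by the floor. All hypothesis tests in this package
are null-relative (observed k′ vs the same estimator applied to shuffled
data), where the floor is common-mode and cancels; absolute k′ values
should be read with the floor in mind.

## Prediction analyses

Tone-33 windowed activity (pitch pinned at 440 Hz) is regressed on p34*
(Hz by default; log switch provided), pooling all trials of a condition.
Group predictive-processing clusters: per-sensor one-sample t across
subjects' slopes, threshold p < 0.05 uncorrected, same-sign spatial
clusters scored by |Σt| against a max-statistic null built by shuffling
the trial pairing of activity and p34* within subject (order shared across
sensors, independent across subjects), 1000 permutations, maxima pooled
across time windows.

The early-sensory spatial filter squares the tone-locked ERF (all 34
tones, all trials), averages 75–125 ms post onset, and normalizes sensor
contributions to sum to 1; the filter is applied to non-squared signals.
ERF contrasts low-pass at 35 Hz (4th-order Butterworth, forward–backward —
zero phase avoids latency distortion in epoch statistics), baseline to the
mean of the 500-ms pre-sequence span, average within low/high-p34* trial
groups, and test the paired difference sample-wise from the offset of the
first tone to the response window, with sign-flip permutations and
contiguous-sample clusters.

## Hypothesis geometry

Group-averaged k′ values from the three duration conditions form vectors
u = (k′₁₅₀, k′₃₀₀, k′₆₀₀) per sensor and shared window (0–150 ms). The
duration line (4, 2, 1) encodes a fixed integration time; the information
line (1, 1, 1) a fixed integrated tone count. Statistics: Euclidean norm
and θ = atan2(‖u×v‖, u·v) ∈ [0, π]; cluster aggregation is the mean of
per-sensor norms/angles (not the stat of the mean vector). Norm is tested
one-tailed high, angle one-tailed low, against 1000 null draws; each draw
picks one shuffle repetition per subject and condition and averages across
subjects. Repetition indices are drawn independently per condition
(configurable to a shared index): the observed triples come from
independent recordings per condition, and coupling the draws cancels
cross-condition shuffle jitter, collapsing the null angle spread.

The null inherits a structural conservatism for the bottom-tail angle test:
all 100 shuffle repetitions of a subject share one frozen recording, so the
null's jitter understates the observed across-subject jitter, and a patch
lying exactly on a line cannot always undercut the null's 5th percentile.
The duration-line discrimination is unaffected because the planted tilt
exceeds the null's tilt.

2-D embedding: points are projected to the plane spanned by the two lines
by standard signed orthogonal projection u − (u·N/N·N)N, N = v_dur×v_info;
a variant with an absolute value on the normal coefficient —
which moves points on one side of the plane away from it — is available
behind a `literal` flag for comparison, and is not used by any analysis.

Array-wide scans compare each sensor's norm/angle to its own null draws,
form clusters of uncorrected p < 0.05 (angles: unusually small, handled by
negating the statistic inside the standard max-statistic machinery and
reporting on the original scale), and score them against the per-draw max
cluster statistic. Cluster p-values are raw proportions (#null ≥ observed
/ n; ties count against significance); a (k+1)/(n+1) smoothed option
exists. d_cluster = (observed − null mean)/null SD.

## Behavioral analyses

Single-subject: fixed-effects three-way factorial ANOVA (tone duration ×
p34* bin × presented final) on trial-level ratings; the p34*×p34
interaction F is the subject's sensory-history index. Group: within-subject
RM-ANOVA on per-subject cell means, error terms = effect×subject
interactions, with Greenhouse–Geisser ε from the covariance of orthonormal
(Helmert) within-subject contrasts, clamped to [1/df, 1] and applied
whenever ε < 1 (Mauchly's test omitted; always correcting is conservative).
Partial η² = SS_effect/(SS_effect + SS_error). Both use an exact balanced
sum-of-squares decomposition (types coincide); unbalanced designs are
rejected.

Brain–behavior: k′ averaged over the three conditions and the cluster's
sensors per subject, Spearman-correlated with the interaction F across
subjects per shared window, Benjamini–Hochberg FDR across windows
(average-rank ties). The sensor-wise variant correlates condition-averaged
k′ maps with F, builds the null by redrawing one shuffle repetition per
subject 1000 times, and applies two-tailed sign-split cluster correction
(|Σρ|, top 2.5th percentile convention).

## Problem sizes

The test suite and the acceptance script run: 12 subjects × 3 conditions
on an 8×8 array (fixed truth; k′, geometry, predictive clusters,
calibration), 12 subjects on a 6×6 array (coupled truth; brain–behavior),
60 replicate null datasets at 500 permutations for family-wise-error
calibration, and 200 series of length 4096 per β for spectral fidelity.
These sizes were chosen as the smallest at which the group-level effects
and calibration checks are stable.

## Numerical notes

- Selection ties: SSE comparisons carry a relative tolerance of 1e−9
  scaled by the test-fold energy, so models that fit exactly tie and the
  smallest k′ wins (required for exact-fit degenerate inputs; irrelevant
  at any realistic noise level).
- Recordings are float32; analysis accumulations are float64.
- The sign-flip ERF permutation exploits that flips leave per-subject
  squares unchanged, so permuted t-maps need only the flipped means.
- All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give bit-identical stimuli, sessions, fits, and nulls.
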