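# tonepred

Analysis pipeline for a question in auditory cognitive neuroscience: when
a predictable tone sequence is played faster or slower, does the brain
integrate past tones over a **fixed time window** (so the number of
integrated tones scales with presentation rate) or over a **fixed amount
of information** (a constant number of tones)? The package implements the
full analysis chain for sensor-array (MEG-like) recordings of listeners
hearing naturalistic 34-tone sequences at 150/300/600 ms per tone, plus a
synthetic-data generator with planted ground truth so every stage can be
validated end to end.

## What it computes

**Stimuli.** Tone pitches follow a stationary Gaussian process with
temporal power spectrum P(f) ∝ 1/f^β (β ∈ {0.5, 0.99, 1.5}), synthesized
by circulant embedding, scaled to 220–880 Hz, and snapped to a 25-value
semitone grid; the penultimate tone is pinned at 440 Hz. The theoretically
predicted final pitch p34\* is the best linear predictor of element 34
given elements 1–33 under the synthesis autocovariance (Toeplitz normal
equations on mean-centered log pitch). The presented final pitch p34 is
drawn independently from six fixed values (±4, 8, 12 semitones).

**Sensory-history integration.** For each sensor and 50-ms window,
activity at tones 16–32 is regressed on the current and k′ previous
pitches (k′ = 0..15); k′ is selected by six-fold cross-validated test SSE
and compared against a null in which tone order is shuffled within each
sequence (current tone preserved, 100 repetitions).

**Hypothesis geometry.** k′ values from the three presentation rates form
a vector u = (k′₁₅₀, k′₃₀₀, k′₆₀₀). Fixed-duration integration predicts u
along (4, 2, 1); fixed-information integration along (1, 1, 1). Vectors
are summarized by the norm ‖u‖ and the angle θ = atan2(‖u×v‖, u·v) to each
line, tested against the shuffled null, with optional projection onto the
plane spanned by the two lines.

**Prediction and behavior.** Tone-33 activity is regressed on p34\* to
find predictive-processing sensor clusters (cluster-based permutation
test, max-statistic null); ERF contrasts trace the predictive build-up;
an M100 spatial filter isolates early sensory processing. Likelihood
ratings are analyzed by factorial/repeated-measures ANOVA
(Greenhouse–Geisser corrected), and the per-subject p34\*×p34 interaction
F is correlated with neural k′ across subjects (Spearman, FDR and
cluster-permutation control).

## Worked example

```python
import numpy as np
import tonepred.stimuli as st
import tonepred.synthetic_data as sd
import tonepred.shi as shi
import tonepred.geometry as geo

stimset = st.build_stimulus_set(seed=7)         # 9 templates (3 beta x 3 bins)
trials = st.assign_final_tones(stimset, seed=1)  # 324-trial design
layout = sd.make_grid_layout(n_side=8)           # 64 sensors, 4 role patches
study = sd.simulate_study(stimset, trials, n_subjects=12, layout=layout,
                          seed=42)

kmaps = {d: [] for d in (150, 300, 600)}
knulls = {d: [] for d in (150, 300, 600)}
for s in range(study.n_subjects):
    recordings, behavior = study.subject_session(s)
    for d in (150, 300, 600):
        wa = shi.window_average(recordings[d], trials)
        kmaps[d].append(shi.fit_kprime(wa, stimset, seed=100 + s,
                                       windows=np.arange(3)))
        knulls[d].append(shi.fit_kprime_shuffled(wa, stimset, n_rep=100,
                                                 seed=100 + s,
                                                 windows=np.arange(3)))

res = geo.cluster_geometry_test(kmaps, knulls,
                                layout.role_idx("temporal"), window=0)
print(f"norm {res['norm']:.2f} (p={res['norm_p']:.3f}), "
      f"angle to duration line {res['angle_duration']:.3f} "
      f"(p={res['angle_duration_p']:.3f}), "
      f"angle to information line {res['angle_info']:.3f} "
      f"(p={res['angle_info_p']:.3f})")
```

Output:

```
norm 12.58 (p=0.000), angle to duration line 0.272 (p=0.001), angle to information line 0.223 (p=0.999)
```

Read: the temporal-role sensors (planted to integrate a fixed 1200 ms, i.e.
8/4/2 tones at the three rates) carry far more history information than
their shuffled null (norm p < 0.001), lie significantly closer to the
duration line than chance (angle p < 0.001), and show no such effect for
the information line — the geometry correctly identifies fixed-duration
integration. Absolute k′ values sit above the planted orders because
cross-validated arg-min selection has a known noise floor (see
`docs/methods.md`); all inference is relative to the shuffled null, where
the floor cancels.

A thin CLI covers data generation: `tonepred stimgen --seed 7 --out dir/`
writes the trial table (and optionally WAV audio of each sequence);
`tonepred simulate --trials dir/trials.csv --subjects 12 --seed 42 --out
dir/` writes HDF5 recordings and behavior tables.

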