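# Methods

This note documents the models, parameter choices, and numerical decisions
behind `emodecode`, and what its synthetic-data tests do and do not
establish.

## The synthetic world

The generator emulates a two-group vocal-emotion EEG experiment at the level
of its statistical structure, not its physiology. Per subject it produces
trials × channels × timepoints arrays (default 624 × 68 × 600: 64 scalp +
4 EOG channels at 500 Hz over −200..1000 ms) composed of three parts:

1. **Pink (1/f^α) noise**, default sd 5 µV per trace with α = 1, generated by
   shaping white noise in the rFFT domain with a 1/f^(α/2) amplitude filter
   (DC zeroed) and rescaling each trace to the target sd exactly. Scalp EEG
   background activity is dominated by a 1/f-like spectrum, and the decoder
   must cope with its strong temporal autocorrelation.
2. **White sensor noise**, default sd 2 µV.
3. **Class-discriminative effects.** Each effect entry names a (group,
   morph-condition) cell, a time window, and an amplitude. Within the window
   the effect adds `amplitude × topography(emotion)` to every applicable
   trial, under a rectangular envelope (optional raised-cosine ramps; the
   effect waveform is otherwise unconstrained by the design, and rectangular
   makes window-recovery tests sharp). Topographies are drawn once per
   (seed, emotion) from a standard normal over channels and scaled by
   `class_topography_separation` — exchangeable and reproducible, with no
   anatomical claim. Emotion-average trials never receive an effect, so with
   all amplitudes zero the data distribution is identical across emotion
   labels *by construction*.

Optional spatial correlation mixes each channel with a shared noise source:
`√(1−c)·independent + √c·common`, default c = 0.3, giving the across-channel
correlation that average referencing and LDA whitening actually have to
handle in scalp data.

Defaults were chosen once as a realistic stated world: musician-group
effects at 500–900 ms in the full and F0 conditions with amplitude 1 µV and
separation 1 (≈ 0.2 σ per-channel class contrast against the ≈ 5.4 µV
combined noise — small per channel, clearly decodable when pooled over 64
channels), a timbre effect fixed at amplitude 0, and no non-musician
effects. The acquisition rate is set to 500 Hz — above the first 250 Hz
resampling target — so the resampling stage is genuinely exercised.

What the generator does **not** emulate: event-related potentials shared
across classes, eye/muscle artifacts, electrode drift or bridging,
between-subject topography variability (every subject shares the class
topographies; only noise differs), and any acoustics of the stimuli (F0 and
timbre exist purely as condition labels). A green recovery test therefore
establishes that the pipeline localises class information where it was
injected under realistic noise — not that it would survive every artifact
structure of recorded EEG.

### Seed hierarchy

`master_seed → (group, index) → subject.seed → per-stage substreams`
(trial-order stream and noise stream are separate children of
`(master_seed, subject.seed)`). Adding subjects or growing a group never
perturbs existing subjects' data, and every artifact is bit-reproducible.

### Trial sequence

312 stimuli × 2 repetitions = 624 trials: each repetition is an independent
uniform permutation of the full stimulus set, concatenated and cut
sequentially into 8 blocks of 78. Prompt trials are implemented as exactly
`round(0.10 × N)` rows sampled without replacement — a deterministic count
with simple invariants rather than per-trial Bernoulli draws. Prompt trials
stay in the analysis (prompts occur only after voice offset).

## Preprocessing

Chain order: resample to 250 Hz → average reference → drop the 4 EOG
channels → baseline-correct (−200..0 ms) → resample to 100 Hz. No frequency
filtering and no artifact or channel rejection anywhere; the classifier is
left to down-weight noisy channels itself.

- **Resampling** removes the per-trace linear trend, resamples the residual
  with `scipy.signal.resample_poly` (rational factor, kaiser-windowed
  anti-aliasing), and restores the trend evaluated at the new timepoints.
  This preserves DC and slow drifts exactly (asserted to 1e−9) while
  preventing aliasing. Output length is `round(n·target/source)`.
- **Time grid**: samples sit left-aligned at −200, −190, …, 990 ms (bins are
  half-open `[t, t+10)`); "baseline" means samples with t < 0. One 100 Hz
  sample therefore *is* the 10 ms analysis bin — no further within-bin
  averaging.
- Average reference and baseline correction are both linear and
  timepoint-/trial-local, so they commute (tested to 1e−9); the EOG channels
  are excluded from the reference mean and removed before decoding.

## Decoding

Per timepoint, features are the 64 scalp voltages. The LDA pooled
within-class covariance is shrunk as `Σ + λ·mean(diag(Σ))·I` with λ = 0.01 —
the ridge style used by MVPA toolboxes, guaranteeing invertibility at 64
features with a few hundred trials. When the scatter is identically zero
(e.g. duplicated trials), `mean(diag)` is zero and the fallback ridge `λ·I`
keeps the problem solvable. Priors are empirical; prediction is the Gaussian
equal-covariance rule; ties break to the first class in the canonical order
(happiness, pleasure, fear, sadness) via first-maximum argmax.

Leave-one-trial-out is computed exactly but without refitting: removing
trial *i* of class *k* downdates the class mean and pooled scatter in
O(d²) (`S' = S − n_k/(n_k−1)·(x_i−μ_k)(x_i−μ_k)ᵀ`), and only the 64 × 64
solve is repeated per fold. Equality with naive refitting is asserted in the
tests. For the cross-morph schemes the train (full) and test (F0 or timbre)
sets are disjoint by construction, so the model is fit once per timepoint —
the natural reading of a design that trains on full-spectrum stimuli and
probes generalization; whether the original analysis kept a fold structure
there is not determinable, and this interpretation is the documented one.

Emotion-average trials are excluded from every scheme (4-class problem,
chance 0.25). Smoothing is a centered 5-point rolling mean truncated at the
epoch edges (an edge value averages only existing samples).

## Group inference

Timepoint statistic: one-sample t of (accuracy − chance) across subjects
(n−1 sd). TFCE with E = 0.5, H = 2, dh = 0.1 (the canonical defaults),
positive tail only. The null flips the sign of each subject's deviation
curve with probability ½ per iteration; family-wise correction takes the
maximum TFCE across timepoints per iteration and computes add-one p-values
`(1 + #{max ≥ obs})/(n_iter + 1)`, so p is never below 1/(n_iter+1). An
exhaustive mode enumerates all 2^n sign assignments for n ≤ 20 and is the
oracle for the Monte-Carlo path (there `p = #{max ≥ obs}/2^n`, identity
included). Each population × scheme analysis (the 3 × 3 grid) is corrected
separately, mirroring how such results are reported per analysis.

Numerical details:

- **t cap.** Zero-variance timepoints map to t = 0 when the mean deviation
  is 0 and to ±100 otherwise; finite |t| > 100 (possible with very few
  subjects and near-identical curves) is clipped to the same bound. t = 100
  is far beyond any attainable significance, and the bound keeps the TFCE
  threshold loop at ≤ 1000 steps.
- **Threshold grid.** Heights are i·dh for i = 1..⌊max/dh⌋ with a 1e−9·dh
  tolerance in the suprathreshold comparison, so a map value lying exactly
  on a threshold is not lost to one ulp of rounding.
- **Vectorisation.** Sign flips change only the flipped mean (squares are
  invariant), so all null t maps come from one matrix product; TFCE of the
  observed + all null maps is computed in one batch by padding/flattening
  the suprathreshold masks and scattering run lengths with `np.repeat`. A
  12-subject, 60-timepoint test with 1,000 iterations runs in ~40 ms.

## Design choices on open points

- The timepoint-level statistic is not fixed by the design ("average
  performance against the bootstrapped distribution" admits several
  readings); the one-sample t across subjects with a sign-flip null is the
  standard choice for a one-sample decoding design and is what the
  exhaustive oracle verifies.
- Baseline timepoints can be decoded for diagnostics
  (`include_baseline=True`) but are off by default; inference runs on the
  post-onset grid.
- Group sizes are plain parameters (defaults 38 and 39); the package takes
  no stance on recruitment-versus-analysis counts.
- EDF/BDF ingestion is a deliberately minimal reader (fixed-layout header,
  int16/int24 little-endian records, physical scaling, single shared rate)
  because no installed library covers the format; event onsets come from a
  TSV sidecar, and the loader is manifest-driven rather than layout-aware.

## Limitations

- The LDA shrinkage λ is fixed, not cross-validated; with 64 features and
  ≥ ~150 trials this is benign, but very small trial counts would favour a
  tuned or analytic shrinkage.
- TFCE is implemented for 1-D (time) maps only — no channel or
  time-frequency clustering.
- Two-sample (group-difference) permutation tests are out of scope; groups
  are each tested against chance, and "difference" statements are
  qualitative.
- The FWER of the max-TFCE procedure is slightly conservative (add-one
  estimator, discrete null), which the acceptance simulation shows
  (≈ 0.04 at α = 0.05 with 12 subjects).
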