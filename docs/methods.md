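# Methods

## The decoding model

Each acquired EPI volume is a sample `x` of voxel signal changes; the
percept label is `y = sign(w·x + b)` with OBJECT ↦ +1 and LINE ↦ −1 (a
decision value of exactly 0 maps to +1; the tie rule is arbitrary but
fixed).  `w, b` are fit by a soft-margin linear SVM (libsvm via
scikit-learn, tolerance 1e-6 for reproducible coefficients).  The
regularization constant defaults to `C = 1` for within-subject decoding.
Features are band-pass-filtered, zero-centered voxel values; no variance
standardization is applied, so voxels enter in percent-signal-change units.

Labels are derived from the reported percept timeline shifted forward by
the hemodynamic delay (5 s).  A volume acquired over `[kT, (k+1)T)` takes
the state occupying the majority of `[kT − 5, (k+1)T − 5)`; ties go to the
state occupying the earlier part of the window, and volumes whose shifted
window precedes the run start are undefined and excluded from both
training and every accuracy denominator.  At TR 2.5 s the rule reduces to
an exact two-volume index shift.

## Synthetic sessions

The generator emulates the study conditions the pipeline was built for:

| parameter | default | meaning |
|---|---|---|
| run duration | 420 s | one acquisition run |
| TR | 2.0 s (online preset) / 2.5 s (offline preset) | volume sampling |
| dwell distribution | gamma(5.29, 4.26 s) online; gamma(2.00, 7.51 s) offline | percept interval lengths |
| minimum dwell | 2·TR | keeps every interval visible after label shifting |
| effect size | ±1.5% signal change | antagonistic voxel populations |
| noise | AR(1), σ = 0.3%, φ = 0.3 | temporally autocorrelated noise |
| drift | 1%, period 300 s | slow scanner drift |
| vessel amplitude | 12% | sinusoidal large-vessel artifact |
| baseline | 100 | so % signal change = absolute deviation |

One dwell distribution is shared by both states.  The double-gamma HRF
(positive lobe gamma(6,1), undershoot gamma(16,1)/6, support 32 s) peaks at
5 s, consistent with the 5 s label shift; convolution kernels are
normalized so a sustained state plateaus at exactly the configured effect
size.  The drift period sits well below the 1/128 Hz high-pass corner —
that cutoff is standard precisely because scanner drift is spectrally
below it, and a drift placed *at* the corner would survive the filter and
misrepresent what the preprocessing can do.  Defaults place ~200
informative voxels in a 20×20×10 grid (tests use smaller grids with the
same densities); real whole-head data differ in spatial correlation
structure, anatomy, motion and physiological noise, so passing tests
demonstrate correctness of the machinery and recoverability under the
stated SNR, not field performance.

## Offline pipeline

Per session: optional Gaussian smoothing (off by default for synthetic
grids, where planted voxels are spatially random and smoothing only mixes
signal with noise), session-wide exclusion of voxels whose signal change
exceeds 10% of their temporal-mean baseline (strict inequality;
label-independent artifact screening), then per-run zero-centering and
zero-phase Butterworth band-pass (high-pass 1/128 Hz).  Cross-validation
is leave-one-run-out; inside every training fold the low-pass cutoff is
chosen from {1/27, 1/18, 1/12, 1/8} Hz by an inner leave-one-run-out loop
(ties to the lowest cutoff), and univariate selection sees training-fold
data only.

Voxel ranking fits one GLM per run — HRF-convolved boxcar regressors for
the two percepts plus an intercept — and scores the contrast
(object − line) with an F test; per-run F values are averaged across
training runs.  The design is rebuilt from the shifted per-volume labels
(inverting the label shift to reconstruct interval onsets), so permuted
label sequences flow through exactly the same scoring path as reported
ones.  With two conditions this F equals the one-way ANOVA F, which is why
a single code path serves both the offline and online descriptions.

## Online pipeline

Runs 1–2: vessel exclusion, baseline storage (later volumes are centered
by subtraction without recomputation), univariate selection of the 10,000
smallest p-values, first-pass SVM, multivariate refinement keeping voxels
with `|w_k| > 0.1 · max|w|` (absolute weights; the weight sign of a linear
SVM is not interpretable voxel-wise), and retraining on the refined set.
The feature set is frozen afterwards.  From run 3 each volume is centered,
advanced one sample through a causal filter, and classified; a switch
event is emitted whenever the prediction changes (the first prediction has
no predecessor and emits none; the last prediction persists across run
boundaries so events always alternate).  After each completed run the
classifier is retrained on all completed runs.  Latency is reported as
TR + a configured processing delay (default 2.3 s), never measured from
the host clock.

Two filter paths are deliberate:

- **Selection/refinement** on the two completed training runs uses the
  zero-phase fourth-order Butterworth band-pass (1/128–1/16 Hz) — those
  runs are fully acquired, so zero-phase filtering is available and gives
  stable voxel rankings.
- **The streaming path** (and the classifier trained for it) uses a causal
  first-order high-pass at 1/128 Hz with *no* low-pass.  Any causal
  low-pass near 1/16 Hz carries several seconds of group delay exactly in
  the percept band (measured 2–16 s depending on order), which would lag
  every decoded switch by multiple volumes and cap tracking accuracy
  around 0.7 regardless of SNR.  The noise averaging a temporal low-pass
  provides offline is supplied in the loop by spatial pooling across the
  multivariate weight map.  `OnlineConfig.lowpass_hz` restores a causal
  band-pass for comparison.

The loop is causal by construction: outputs for a prefix of the stream are
unchanged by truncating the rest (asserted in tests).

## Permutation statistics

Percept labels are strongly autocorrelated, so chance levels come from
permuting *maximal blocks* of consecutively equal labels: block-length
multisets and per-label volume counts are preserved exactly.  Blocks are
formed within runs (never straddling a boundary) and shuffled across the
whole session; undefined label positions stay in place.  The guessing
level of the decoder reruns the complete cross-validation — feature
selection inside every fold — for each of the permutations (500 by
default) and reports the mean and percentile CI of the null accuracies.

Per-voxel weight significance `p_w` is the fraction of permutations whose
refitted weight magnitude reaches the observed one, ties counting as
exceeding.  Weight vectors are normalized to unit Euclidean norm before
comparison: the decision rule is invariant to a common rescaling of
`(w, b)`, and the overall norm of a regularized fit *shrinks* as class
separation grows, so raw-weight comparisons would paradoxically make
strongly informative voxels look less significant.  On all-null data the
fraction of voxels with `p_w < 0.1` calibrates to ≈0.1; null voxels that
share a dataset with true signal are conservative.  The conjunction mask
requires `p_w < threshold` (strict) in both experiments.

## Cross-subject transfer

Sessions are reduced to one sample per sustained percept: the mean of the
three volumes centered on the interval's middle defined volume
(even-length intervals center on the earlier middle; shorter intervals
contribute what they have, and intervals spanning fewer than three defined
volumes are flagged switch-adjacent).  Per subject, a weight map is
trained on all reduced samples (top-K ANOVA selection) and embedded in the
common grid; `p̂ᵢ` is the subject's own leave-one-run-out accuracy on the
reduced samples.  Maps combine as `w̄_k = (1/n) Σᵢ 2(p̂ᵢ − ½) w_kⁱ`,
applied verbatim (no per-subject norm standardization): a chance-level
subject contributes nothing and a below-chance subject enters with flipped
sign.  Transfer is leave-one-subject-out: combine training maps, keep the
`K` highest-|w̄| voxels, train a fresh classifier on pooled training
samples, and score the held-out subject, who never touches combination or
selection.

The group pipeline uses `C = 0.01` rather than 1: with interval-center
reduction the sample count (~tens to low hundreds) is far below the voxel
count, and at `C = 1` the weight *direction* is dominated by
support-vector noise even when decoding accuracy is high.  Small `C`
makes most samples margin violators, so the fit averages over them
(ridge-like) and the maps are dominated by the shared percept contrast —
which is the quantity map combination assumes.  All simulated subjects
share one voxel grid, standing in for normalization to a common
anatomical space.

## Evaluation

Switch-local decomposition defines the near-switch set as each switch
volume (the first volume of a new true state within a run) plus one
neighbor on each side; the two subsets partition the volumes.  Dwell-time
gamma fits use maximum likelihood (location fixed at 0) for parameter
recovery, or least squares against the normalized duration histogram
(default 3 s bins) with an R² of fit; the pdf mode is `(shape − 1)·scale`
for shape > 1, cross-checked by grid maximization.  Signed t-maps are
pooled-variance two-sample t values (object minus line) on interval-center
samples, with honest degrees of freedom `n − 2`.

## Problem sizes and determinism

Tests and examples run on desk-scale grids (≈250–900 voxels, 4–8 runs)
with the full 420 s run length and the preset dwell statistics; selection
sizes scale with the grid (e.g. top-300 of ~850).  Every stochastic
component takes an explicit seed or `numpy.random.Generator`; identical
seeds reproduce sessions, models, and results bit-for-bit.

## Known limitations

- No motion, physiological noise, slice timing, or anatomical variability
  in the simulator; exclusion of those artifacts is out of scope.
- The GLM assumes the canonical HRF; subject-specific hemodynamics are not
  modeled.
- Online retraining uses reported percepts as ground truth; report latency
  is not modeled by default (`jitter_report_times` can delay and jitter
  reported switch boundaries, but sessions use the true timeline unless
  asked otherwise).
- Transfer assumes voxel correspondence across subjects; real anatomical
  registration error would degrade it.
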