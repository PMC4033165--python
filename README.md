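# percepttrack

Decoding the content of bistable visual perception from fMRI BOLD activity,
volume by volume — offline, and in a simulated real-time loop.

## The problem

When an outline figure moves behind a narrow slit, observers spontaneously
alternate between two conscious percepts of the identical physical
stimulus: vertically jumping **line** segments, or an integrated, occluded
**object** moving horizontally.  Percept dwell times are gamma-distributed;
switches are reported by button press.  The scientific question is whether
whole-head BOLD activation patterns carry enough information to track which
percept a subject is experiencing at each acquired volume — offline with
cross-validation, and online while the scan is running.

`percepttrack` implements the full analysis as a tested, reusable library
for researchers working on multivariate decoding of perceptual states:

- **`synthetic_data`** — bistable-percept BOLD session simulator
  (gamma dwell timelines, double-gamma HRF, antagonistic voxel populations,
  AR(1) noise + drift, >10%-signal-change "vessel" voxels), with NIfTI +
  BIDS-like events I/O;
- **`preprocessing`** — zero-centering, Butterworth band-pass (zero-phase
  and causal), 10%-signal-change voxel exclusion, hemodynamic label
  shifting, Gaussian spatial smoothing;
- **`feature_selection`** — per-voxel GLM contrast *F* ranking
  (HRF-convolved percept regressors), top-*K* retention, multivariate
  weight refinement;
- **`decoding`** — linear max-margin classifier
  `y = sign(w·x + b)`, leave-one-run-out cross-validation with in-fold
  low-pass-cutoff optimization;
- **`online_decoder`** — causal volume-by-volume loop: two training runs,
  streaming prediction with switch events, per-run retraining;
- **`permutation_stats`** — block-preserving label permutations for the
  empirical guessing level (95% CI) and per-voxel weight significance
  `p_w`;
- **`group_transfer`** — interval-center sample reduction, per-subject
  weight maps combined by accuracy weighting
  `w̄_k = (1/n) Σᵢ 2(p̂ᵢ − ½) w_kⁱ`, leave-one-subject-out transfer;
- **`evaluation`** — switch-local accuracy decomposition, gamma dwell-time
  fits (MLE and histogram least squares), signed t-maps, critical values,
  figures.

## Worked example

```python
import numpy as np
from percepttrack import synthetic_data as sd, decoding, online_decoder, evaluation

rng = np.random.default_rng(7)
voxels = sd.default_voxel_spec(grid_shape=(12, 12, 6), n_positive=60,
                               n_negative=60, n_vessel=10, rng=rng)
session = sd.simulate_session(8, sd.ONLINE_PRESET, voxels=voxels,
                              noise=sd.NoiseConfig(sigma=0.3), seed=7)

result = decoding.loro_cv(session, decoding.CvConfig(k_select=300))
overall, away, near = evaluation.switch_local_accuracy(
    result.y_true, result.y_pred, result.run_index)
print(f"offline leave-one-run-out accuracy: {overall:.1%}")
print(f"  away from switches: {away:.1%}   near switches: {near:.1%}")

online = online_decoder.run_session(session,
                                    online_decoder.OnlineConfig(k_initial=300))
print(f"simulated online accuracy (runs 3-8): {online.accuracy:.1%}")
```

prints

```
offline leave-one-run-out accuracy: 89.3%
  away from switches: 95.8%   near switches: 72.0%
simulated online accuracy (runs 3-8): 95.2%
```

The session is an 8-run, 420 s/run simulation at TR 2.0 s with 120 planted
informative voxels (±1.5% signal change, half responding more and half less
during object percepts) against 0.3% AR(1) noise.  Decoding is nearly
perfect away from perceptual switches; errors concentrate in the volumes
around a switch, where the sluggish hemodynamic response is still in
transit between states — exactly the error structure this paradigm
produces on real data.  The online loop emits a switch event whenever the
decoded percept changes, and retrains after every completed run.

A command-line interface wraps the same pipeline:

```bash
percepttrack simulate --preset online --runs 8 --out /tmp/ses --seed 7
percepttrack decode-offline --session /tmp/ses --out /tmp/offline
percepttrack decode-online  --session /tmp/ses --out /tmp/online
percepttrack permtest --session /tmp/ses --n-perm 500 --seed 0 --out /tmp/null
```

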