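# conesubunits

Hierarchical subunit models of retinal ganglion cell light responses at
single-cone resolution.

Retinal ganglion cells (RGCs) do not pool photoreceptor signals linearly:
cone inputs are first combined by bipolar interneurons whose outputs are
rectified before summation at the ganglion cell.  These *nonlinear
subunits* let the retina signal finer spatial structure than the
receptive-field size suggests — they produce frequency-doubled responses
to contrast-reversing gratings and a failure of cancellation when one
cone in a pair is brightened while the other is darkened.  Because
bipolar cells are hard to record from directly, their input structure has
to be *inferred* from ganglion-cell spikes.

This package implements that inference for people modeling
single-cone-resolution recordings (and for anyone who wants a
well-tested, fully synthetic testbed for two-stage cascade estimators):

* the forward model — a linear–nonlinear–linear–nonlinear–Poisson
  cascade,

      y_st = f( Σ_c (I ⊙ A)_sc x_ct ),   z_t = g( Σ_s w_s y_st ),
      r_t ~ Poisson(z_t)

  with a binary cone-to-subunit partition `I` (each cone in exactly one
  subunit), non-negative within-subunit weights `A` (rows sum to 1),
  sign-free subunit weights `w`, and 8-node cubic-spline nonlinearities
  `f`, `g` (C² by construction, linear extrapolation);
* maximum-likelihood fitting: coordinate descent over (w, A, f) with `g`
  refit once at the end, nested in a greedy agglomerative search over
  subunit merges starting from the single-cone model;
* the LN and single-cone-subunit reductions, fitted by the same
  machinery, as comparison baselines;
* a synthetic-data module (mosaics, binary and aperture-filtered cone
  noise, contrast-reversing gratings, targeted single/paired-cone
  trials, repeated noise blocks, ground-truth models) so the whole
  method is testable by parameter recovery;
* evaluation metrics: cross-validated R², reliability-adjusted R²,
  maximally-differentiating-stimulus selection, improvement slopes,
  grating cycle averages with F1/F2 amplitudes, paired-cone response
  normalization and scoring, and a bootstrap model-comparison test.

See `docs/methods.md` for the model, fitting, and design details.

## Worked example

Simulate a 5-cone OFF cell in which two cones share a subunit, fit the
model from scratch, and compare it with an LN fit:

```python
import conesubunits as cs

truth = cs.default_ground_truth(n_cones=5, multi_cone_sizes=(2,), seed=0)
print("true partition:  ", [sorted(map(int, s)) for s in truth.assignment.cone_sets()])

stim = cs.aperture_noise_cone_stimulus(5, duration_min=8.0, seed=1)
counts = cs.simulate_spikes(truth, stim, seed=2)
print(f"simulated {stim.n_frames} frames, mean rate "
      f"{counts.counts.mean():.2f} spikes/frame")

config = cs.FitConfig(seed=3)
result = cs.greedy_fit(stim, counts, config)
print("fitted partition:", [sorted(map(int, s)) for s in result.model.assignment.cone_sets()])
print("subunit sizes:   ", cs.subunit_size_distribution(result.model))

ln = cs.fit_ln(stim, counts, config, train_idx=result.train_idx)
test = result.test_idx
r2_sub = cs.r_squared(cs.firing_rate(result.model, stim)[test], counts.counts[test])
r2_ln = cs.r_squared(cs.ln_predict(ln, stim)[test], counts.counts[test])
print(f"held-out R^2: subunit {r2_sub:.3f}  vs  LN {r2_ln:.3f}")
```

Output:

```
true partition:   [[0, 1], [2], [3], [4]]
simulated 5760 frames, mean rate 1.04 spikes/frame
fitted partition: [[0, 1], [2], [3], [4]]
subunit sizes:    {1: 3, 2: 1}
held-out R^2: subunit 0.381  vs  LN 0.319
```

The greedy search recovers the true cone partition exactly from eight
minutes of simulated noise responses, and the fitted cascade predicts
held-out spike counts better than the LN baseline — the gap is modest on
white noise (which only rarely drives the two models apart) and widens
sharply on structured stimuli such as fine gratings and targeted paired
increments/decrements; see the studies in `conesubunits.studies`.

A command-line interface covers the same workflow on files
(`conesubunits simulate | fit | recover | evaluate | predict-gratings |
predict-pairs`); stimuli travel as HDF5 (CSV fallback), models as JSON,
mosaics as CSV, and every run writes a manifest with the config hash and
seed.

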