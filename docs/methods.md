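# Methods

## The model

`conesubunits` implements a two-stage cascade model of retinal ganglion
cell (RGC) light responses operating at the resolution of individual cone
photoreceptors — a linear–nonlinear–linear–nonlinear–Poisson (LN-LN-P)
cascade.  The `C` cones feeding a cell's receptive field are partitioned
into `S` non-overlapping *subunits*, the functional correlates of (midget)
bipolar cells:

    y_st = f( sum_c (I ⊙ A)_sc · x_ct )          subunit outputs
    z_t  = g( sum_s w_s · y_st )                 firing rate
    r_t  ~ Poisson(z_t)                          spike counts per frame

where `x_ct` is the cone-input stimulus (contrast units), `I` is a binary
S×C indicator matrix whose columns each sum to 1 (each cone drives exactly
one subunit), `A` holds non-negative within-subunit cone weights with each
row summing to 1, `w` is a sign-unconstrained subunit weight vector, and
`f`, `g` are smooth scalar nonlinearities shared across subunits.  With
`I = A = identity` and linear `f` the cascade reduces exactly to the
classic LN model; with `I = identity` and free `f` it is the "single-cone
subunit" model.  These two reductions are the baselines every comparison
uses.

The log likelihood is the Poisson form `Σ r_t log z_t − Σ z_t`; the
`log r_t!` constant is omitted since it never depends on parameters.
Rates are floored at `ε = 1e−6` spikes/frame before the log (the spline
`g` is not constrained to be positive).

## Nonlinearities

`f` and `g` are cubic splines with eight nodes, parameterized by their
eight nodal values and interpolated with the *natural* cubic spline (zero
second derivative at the end nodes).  This construction is C² at every
interior node for any coefficient vector, so the smoothness constraints
are built into the parameterization rather than imposed as explicit
linear constraints.  Beyond the end nodes the spline continues linearly
along the end tangents, which keeps it C² at the junctions and prevents
cubic blow-up when the fitted drive distribution shifts.

Because natural-spline interpolation is linear in the nodal values, the
spline value at any point is an inner product of a fixed basis row with
the 8-vector of parameters (`SplineBasis.design_matrix`).  Likelihood
sub-fits of `f` and `g` are therefore smooth 8-dimensional optimizations
with analytic gradients (L-BFGS, 50 iterations, relative tolerance 1e−6).
Nodes are placed uniformly between the 1st and 99th percentiles of the
empirical drive distribution at the time of each sub-fit; if moving the
nodes lowers the likelihood, the incoming spline is kept, so the trace
stays monotone.

Initial shapes: `g` starts as softplus `log(1+exp(v))`; `f` starts as
negative half-wave rectification `min(v, 0)`.  The sign flip needed for
OFF-type cells is carried by `w`, which is unconstrained in sign.

## Fitting

Estimation separates the combinatorial and continuous parts of the
problem:

* **Continuous parameters** (`w`, `A`, `f`) are optimized by coordinate
  descent in the order w → A → f, repeated until the training
  log-likelihood improves by less than 1e−6 (relative) or 15 rounds.
  The w-step is a standard LNP weight fit (L-BFGS with analytic
  gradients); the A-step parameterizes each multi-cone row of `A` by
  softmax logits, which satisfies positivity and row-sum-1 exactly while
  keeping the inner problem smooth and unconstrained; the f-step is the
  spline sub-fit above.  `g` is refit only once, at the very end.  Every
  sub-step keeps the better of {incoming, optimized} parameters, so the
  log-likelihood trace is non-decreasing by construction.  A zero-variance
  stimulus is detected up front and returned unfit with a flag.

* **The assignment** `I` is found greedily: starting from the identity
  (single-cone subunit model), all S(S−1)/2 candidate pair-merges are
  evaluated by refitting the continuous parameters warm-started from the
  current fit with a reduced budget (5 outer rounds); the best pair is
  merged iff its maximized training likelihood exceeds the current
  model's, and the accepted merge is then refit to full tolerance.  The
  search stops when no pairing improves the likelihood — at most C−1
  merges.  Before each candidate round the unmerged model receives the
  same extra optimization budget, so refinement of shared parameters
  cannot masquerade as a merge improvement.  During the search `g` stays
  at its initialization (all candidates compared under the same `g`); it
  is refit once after termination.  Warm starts for a merged pair:
  the merged `A` row concatenates the parents' weights scaled by their
  |w| and renormalized; the merged `w` entry takes the larger-|w|
  parent's value.  Ties between equal-likelihood pairs resolve to the
  lowest (s1, s2) index pair.

Train/test splitting holds out contiguous blocks (≈1 minute each, default
720 frames at 12 Hz; shrunk to T/10 for short recordings) at random
positions, so the held-out fraction (default 20%) is distributed across
the recording rather than drawn frame-wise.

Everything is deterministic given the configuration seed.

## Synthetic data

The generator produces every input the pipeline consumes, so the whole
method is validated by parameter recovery without recordings:

* **Cone mosaics** — jittered square lattices (default spacing 8 µm,
  Gaussian aperture σ 2.5 µm).
* **Binary cone noise** — i.i.d. ±96% contrast per cone per frame at
  12 Hz, the nominal stimulation regime.
* **Aperture-filtered noise** — each cone input drawn as a normalized
  Gaussian-aperture-weighted sum of i.i.d. binary ±96% pixels (3.4 µm
  pixels), the marginal distribution obtained by projecting a
  high-resolution binary noise movie through the cone apertures.  This is
  the generator the fitting studies use: with strictly binary per-cone
  inputs the assignment is *not identifiable* — a wrongly merged pair
  produces drive on only four support points and the 8-node spline can
  reproduce the unmerged model's rates exactly there, so wrong merges win
  by overfitting.  Continuous-valued cone inputs (as produced by real
  preprocessing) restore identifiability.
* **Gratings** — contrast-reversing sinusoids at 2 Hz, eight spatial
  phases, 8 s presentations followed by 2 s of mean gray, three repeats
  by default; the Gaussian aperture filters the spatial sinusoid in
  closed form (attenuation `exp(−2π²σ²/λ²)`), verified against 2-D
  quadrature.  A square-wave temporal-modulation flag is available.
* **Targeted trials** — 750 ms trials with a 250 ms stimulus window in
  which one or two chosen cones receive ±contrast scaled by the analytic
  spot/aperture overlap `1 − exp(−R²/2σ²)` (spot radius default 8.5 µm).
* **Repeated noise blocks** — one frozen noise sequence (default 10 s)
  with independent Poisson draws per repeat, for reliability-adjusted
  accuracy.
* **Ground-truth models** — OFF-polarity cells with a chosen partition
  (default: two 2-cone subunits plus single-cone subunits), rectifying
  `f` with 0 placed exactly on a node (an interpolation bulge at 0 would
  leak into the spontaneous rate through every subunit), within-subunit
  weights drawn comparable (1 ± 0.15 before normalization), and a shifted
  softplus `g` scaled so mean rates sit near 1 spike/frame (~12 spikes/s)
  with a low spontaneous rate — typical OFF-midget numbers.

The STA-based temporal alignment needed for real pixel movies
(`sta_temporal_align`, rank-1 SVD of the spatiotemporal STA) is provided
but bypassed in synthetic mode, which generates directly at frame
resolution.  What the generator does *not* emulate: temporal filtering and
latency, adaptation and gain control, receptive-field surrounds,
spike-history effects, cone noise correlations, and recording
nonstationarities.  Passing the recovery studies therefore demonstrates
the estimator's correctness under the model's own assumptions, not
robustness to those real-data complications.

## Evaluation metrics

* `r_squared` — 1 − SSE/SST against held-out counts; ≤ 1, can be
  negative.
* `select_max_diff_frames` — the ⌊0.2·T⌋ held-out frames with the largest
  squared difference between two models' predictions (ties broken by
  ascending frame index).  Selection reads only the predictions, never
  the observations, so it cannot bias the subsequent comparison.
* `improvement_slope` — through-origin regression slope of one model's
  per-cell R² on another's; cells with negative reference R² are excluded
  (only relevant for max-diff analyses).
* `adjusted_r_squared` — mean over trials of corr²(prediction, trial)
  divided by mean corr²(trial, mean of remaining trials); gain/offset
  invariant by construction.  A flat prediction scores corr 0 (it
  explains nothing); trials with zero variance are skipped with a
  warning.
* `cycle_average` / `f1_f2_amplitudes` — responses folded over one
  temporal-modulation period (bin width = one stimulus frame) and the DFT
  amplitudes at the first and second harmonics.  F2 > F1 at the null
  phase is the frequency-doubling signature of rectified subunits.
* `paired_response_table` / `paired_prediction_score` — each tested
  cone's four condition rates (single decrement + three pairings,
  averaged over repeats in a 300 ms window from stimulus onset, which
  spans four 83 ms bins) normalized by their maximum; accuracy is the
  squared correlation between measured and predicted normalized
  responses pooled over cone pairs (the pairing entries; the single-cone
  condition serves as each table's normalizer).
* `bootstrap_model_comparison` — cone pairs resampled with replacement
  (default 10,000 iterations), accuracies re-estimated per draw, and a
  difference declared significant iff the 5th percentile of its bootstrap
  distribution exceeds 0.
* `cancellation_index` — paired/single response ratio with the ≥ 0.5
  threshold separating non-cancelling (across-subunit) from cancelling
  (within-subunit) cone pairs.

## Simulation studies and problem sizes

`run_recovery` simulates an 8-cone ground truth (subunit sizes
{2,2,1,1,1,1}) at 4, 8, and 16 minutes of 12 Hz frames, five seeds each,
and refits from scratch.  Reported: exact-partition recovery rate,
cone-weight RMS error, nonlinearity shape error (after a free scale
alignment, since the scale of `f` trades off against `w`), and rate RMS
on fresh noise.  When the fitted partition differs from the truth the
true assignment is refit to define the weight and nonlinearity errors.

`grating_frequency_doubling_study` uses a four-cone, two-subunit ground
truth with the two subunits at distinct grating-axis positions (8 µm
apart, fixed sub-micron jitter as in real mosaics), σ = 2 µm apertures,
30 minutes of aperture-filtered noise for fitting, and a period battery
of 13–64 µm chosen incommensurate with the lattice: at a period equal to
the subunit separation both subunits see identical drive, and at twice
the separation the LN model's output-nonlinearity curvature reproduces
the frequency-doubled shape, so commensurate periods cannot separate the
models even in principle.  Grating trials use 60 simulated repeats for
estimator power (the generator's protocol default remains 3 repeats).
The null phase is the presented phase minimizing the fitted LN model's
drive.

`closed_loop_validation_study` simulates five cells (8 cones, two 2-cone
subunits each), fits the full subunit, single-cone-subunit, and LN models
to 8 minutes of noise per cell, then scores all three on targeted paired
increment/decrement trials: four tested cones per cell, each paired with
its within-subunit partner and two across-subunit cones (12 pairs per
cell, 60 total), 30 Poisson trial repeats for the "measured" tables.

These sizes were chosen to keep each study well-powered while the full
suite (unit + acceptance tests) runs in a few minutes on one CPU; the
16-minute/5-seed recovery grid mirrors the durations at which assignment
recovery is expected to saturate.

## Known limitations

* Greedy merging with a strict accept-if-improved rule can accept
  likelihood-neutral merges on small overfit fluctuations when the data
  genuinely contain no multi-cone structure (e.g. a linear-`f` LN ground
  truth); such merges are noise-scale in ΔLL and do not change predictive
  accuracy.
* No split or swap moves in the assignment search; a wrong early merge
  can only be diluted, not undone.
* Identifiability of `f` is limited to the support of the fitted drive
  distribution; with discrete-valued stimuli the spline between support
  points stays at its initialization.
* The candidate-merge refits use a reduced budget; a merge whose benefit
  only appears after full convergence could in principle be missed.
* Spike generation is inhomogeneous Poisson per frame: no refractoriness,
  bursting, or history dependence.
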