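# Methods

## The model

`lnlncascade` fits two-layer linear-nonlinear (LN-LN) cascade models of
sensory neurons.  A spatiotemporal stimulus vector **x** (a window of a
1-D bar movie, embedded over `n_lags` frames of history) drives k hidden
subunits.  Subunit i filters the stimulus with a unit-norm spatiotemporal
filter **w**_i and passes the projection through a flexible scalar
nonlinearity h_i; the subunit outputs are summed and passed through a soft
rectifier:

    r(x) = g · log(1 + exp( Σ_i h_i(w_i·x) − θ ))

The firing rate r drives Poisson spiking.  Each h_i is parameterized as a
weighted sum of p = 30 evenly spaced Gaussian bumps, which enforces
smoothness while leaving the shape free; the LN model is the k = 1 special
case.  Because the filters are unit-norm and the white-noise stimulus has
unit variance, the input to every subunit nonlinearity is standard normal,
so nonlinearities of different cells and subunits live on a common axis
measured in stimulus standard deviations.

Assumptions: spiking is conditionally Poisson given the stimulus; the
response is stationary (no adaptation, no spike history); subunits combine
additively before a single output nonlinearity.

## Fitting

Parameters are learned by maximizing the Poisson log-likelihood with
regularization, alternating over three blocks until the validation
likelihood stalls (relative change < 1e-4 over two rounds, capped at the
`max_rounds` setting):

1. **Subunit filters** — proximal consensus (ADMM).  The objective is the
   sum of a smooth data term (the negative log-likelihood divided by the
   number of training spikes, which makes curvature and penalty scales
   independent of recording length and firing rate), an l1 penalty
   (sparsity), and a nuclear-norm penalty on each filter reshaped to its
   (n_bars × n_lags) spatiotemporal matrix (approximate space-time
   separability).  Each term owns a variable copy driven by its proximal
   operator; copies are averaged with dual corrections.  The data term's
   proximal step has no closed form and is solved by L-BFGS, warm-started
   from the previous solution; dual variables are also carried across
   rounds.  After the block, filters are rescaled to unit norm and the
   norm is absorbed into the input scale of the corresponding nonlinearity
   (by least-squares re-projection onto the bump basis).
2. **Subunit nonlinearities** — penalized Poisson regression of the bump
   weights on the (fixed) subunit activations, with a small ridge (1e-4)
   for conditioning and a second-difference smoothness penalty
   (`nl_smooth`, default 30 on the summed-NLL scale).  The smoothness term
   matters beyond aesthetics: wiggles in h feed h' into every filter
   gradient, and damping them measurably improves filter recovery.
3. **Output stage** — quasi-Newton fit of (log g, θ); the log
   parameterization keeps the gain positive.

Per-round train/validation likelihoods are recorded in `report_`; the
round with the best validation likelihood is kept.  The regularized
training objective is monitored and a flag (`uphill_flag_`) is raised if
it ever increases by more than 1e-3 relative per round.

### Initialization

Random Gaussian filter initialization makes the alternating scheme prone
to a symmetric collapse: every filter receives the same initial gradient
signal and converges to the population-average (STA-like) direction.  The
default `init="spectral"` therefore seeds the filters with mixtures of the
*regularized* spike-triggered average (the pathway mean) and the leading
*regularized* spike-triggered covariance eigenvectors (the pathway
differences): filter j starts at b0 + cos(2πj/k)·b1 + sin(2πj/k)·b2 with
b0 the denoised STA direction and b1, b2 denoised STC directions
orthogonalized against it, plus a small random jitter.  `init="random"`
and explicit (k × N) arrays remain available.

### Penalty weights and the polish stage

The default weights (γ_l1 = 0.02, γ_nuc = 0.05 on the per-spike objective)
were fixed once by cross-validation on the standard synthetic fixture and
then held constant, mirroring the practice of choosing weights on a small
subset of cells and freezing them.  A grid utility
(`lnlncascade.lnln.penalty_grid`) spans three orders of magnitude for
users who want to recalibrate.

Penalties strong enough to guide the nonconvex search also bias the
recovered filters toward zero (soft-thresholding shrinks true
coefficients, not just noise; singular-value thresholding shrinks the
weaker space-time component of a near-separable filter most of all).  The
fit therefore ends with three guarded refinement stages, each kept only if
it improves the held-out likelihood:

1. **Polish** — a short warm-started refit with the penalty weights
   multiplied by `polish_factor` (default 0.25), the proximal analogue of
   the relaxed lasso: the strongly penalized stage finds the
   support/subspace, the weakly penalized stage debiases within it.
2. **Fixed-rank refinement** (`lowrank_rank`, default 2) — each filter is
   re-parameterized as a rank-2 factorization U Vᵀ and all parameters are
   refit jointly by L-BFGS on the unpenalized per-spike likelihood.  This
   removes the nuclear-norm shrinkage exactly where it bites while keeping
   the low-dimensional structure that motivated the penalty.  The
   trajectory is **early-stopped**: held-out likelihood is evaluated at
   every iterate and the best one is returned (unpenalized descent
   overfits within tens of iterations at these spike counts, and the best
   validation iterate is the implicitly regularized estimate).  The stage
   is repeated (fresh quasi-Newton state) while validation keeps
   improving, up to three cycles.
3. **Joint refinement** — the same early-stopped joint L-BFGS over the
   unconstrained parameters, which can escape points that are optimal per
   block but not jointly.

Finally, redundant subunits are pruned by backward elimination
(`prune_subunits`): each subunit in turn is silenced (its bump weights set
to zero, making its nonlinearity exactly flat), the remaining
nonlinearities and output stage are refit, and the silencing is kept only
if the held-out likelihood improves.  A model given more subunits than the
cell needs therefore ignores the extras — their nonlinearities come out
flat — instead of splitting a real pathway across two filters, and
genuine subunits are protected because silencing them costs held-out
likelihood.

### Subspace estimation across folds

When the quantity of interest is the subunit filter *subspace* rather than
one fitted model, `fit_subunit_subspace` fits the cascade on a few rotated
train/validation splits of the recording and averages the projectors onto
each fit's filter span (taking the top-k eigenvectors of the average).
Individual fits at desk-scale spike counts land on the data's
likelihood-indifference set around the true filters with partially
independent errors across splits, so the fold average has measurably lower
subspace error than any single fit.

### Choosing the number of subunits

`select_num_subunits` fits models of increasing k and scores each on
held-out data in bits/spike; fitting stops as soon as the score drops
below the running best (beyond a 1e-3 bits/spike tolerance), and among
ties within that tolerance the smallest k is returned.  Fitting k larger
than the true subunit count is benign: superfluous subunits come out with
near-flat nonlinearities and do not modulate the output.

## Regularized spike-triggered statistics

For a Gaussian white-noise stimulus the STA is proportional to the average
gradient of the response function and the STC to its average Hessian
(Stein's lemma), so for any k-pathway cascade the STA is a linear
combination of the pathway filters and the significant STC eigenvectors
span them.  The same structural priors used in fitting therefore apply to
the statistics themselves:

- `regularized_sta` solves ``argmin ||x − sta||² + γ1||x||₁ + γ*||X||_*``
  by proximal consensus, needing only the raw STA.
  `suggested_sta_penalties` sets the weights from the noise scale: the raw
  STA has i.i.d. noise of s.d. σ = 1/√n_spikes per coordinate, so the
  nuclear threshold is placed at the Marchenko–Pastur edge
  σ(√n_bars + √n_lags) of a pure-noise matrix and the l1 weight at σ.
- `regularized_stc` maximizes Tr(XC) minus elementwise-l1 and column-wise
  nuclear penalties over the fantope F_d = {0 ⪯ X ⪯ I, tr X = d} (the
  convex hull of rank-d projectors), via consensus ADMM with the
  closed-form linear-term prox (v + C/ρ) and an exact fantope projection
  (eigenvalue projection onto the capped simplex by bisection, trace
  tolerance 1e-10).  The consensus average is projected onto the fantope
  at the end so feasibility holds exactly, and a final eigendecomposition
  returns the top-d orthonormal directions.  Setting ``suppressive=True``
  negates C to find suppressive directions.

Significance of *raw* STC eigenvectors (needed as a baseline) uses a null
band from circular shifts of the spike train against the stimulus —
standard practice, chosen here because no canonical criterion exists.

## Numerical choices

- ADMM: ρ = 1 held constant; stopping when the scaled primal residual
  max_i‖x_i − x̄‖/√N and dual residual ‖Δx̄‖/√N both fall below 1e-4
  (1e-5 for the fantope program); iteration caps 250 (standalone solves)
  or 10–20 (inside a fit round, where dual warm starts carry progress
  across rounds).
- Smooth-loss prox: L-BFGS, 50-iteration cap standalone, 6–8 inside fit
  rounds (warm-started).
- Rate evaluation uses log-domain softplus throughout and is stable for
  drives |Σh − θ| up to 700; rates are floored at 1e-300 to keep
  logarithms finite.
- Bump basis: 30 centers tiling [−5, 5] input s.d., width equal to the
  spacing.  The tiling range follows from the unit-variance projection
  property.
- Degenerate cases raise rather than guess: zero spikes, flat
  nonlinearities (the threshold statistic has a dedicated
  `FlatNonlinearityError`), rank-deficient subspaces, asymmetric
  covariance inputs.
- The 40%-of-maximum nonlinearity threshold is computed min-subtracted on
  a 1e-3 grid over [−5, 5].
- Difference-of-Gaussians receptive-field fits parameterize the surround
  width as a multiple (> 1.05) of the center width, making σ_c < σ_s
  structural, and add a very weak surround-amplitude penalty so a pure
  Gaussian resolves to "no surround" instead of an arbitrary
  decomposition.  Center/surround "size" is reported as 2σ (no standard
  definition exists; axes elsewhere rarely state one).
- The spatial profile of a spatiotemporal filter is its leading
  left-singular vector, sign-aligned so the dominant lobe is positive.

## The synthetic fixture

The generator emulates the experimental stimulus: 100 Hz Gaussian white
noise bars (50 bars × 55.5 μm by default, spanning ≈ 2.8 mm of retina),
plus a naturalistic control (spatially pink noise, 1/f spatial power with
random phases, temporally low-passed at 2 Hz, unit variance).  Ground-truth
cells combine difference-of-Gaussians spatial profiles (σ_c = 55 μm,
σ_s = 165 μm) with biphasic temporal kernels (two gamma-like lobes, the
surround time course slightly delayed so the filter's stable rank is ~1.1,
i.e. nearly but not exactly space-time separable), high-threshold softplus
subunit nonlinearities calibrated so the 40%-of-max statistic lands at the
stated threshold (3 s.d. by default), and a soft-rectifier output.

The standard two-subunit fixture places two Off-type subunits 10 bars
apart on a 20-bar window with 15 frames (150 ms) of temporal history and
an output stage producing ≈ 2 spikes/s — the sparse-firing, high-threshold
regime of interest.  The 20 × 15 embedding (300 parameters per filter) is
the package's choice of problem size: it keeps a full model fit on 10⁵
bins in the minutes range on a single core while preserving every
qualitative property under study (center-surround geometry, near-separable
kinetics, OR-like thresholding, 1–2 spikes/s).  Recovery scores at this
scale should not be read as guarantees for larger embeddings, where the
same spike budget is spread over many more parameters.

What the generator does not emulate: photoreceptor/bipolar adaptation,
spike-history dependence, recorded-cell heterogeneity, non-Poisson count
dispersion, and eye/stage movement artifacts.  Passing recovery tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to their violation.

## Known limitations

- The alternating scheme is nonconvex; the spectral initialization makes
  it reliable on the fixture family, but pathological cells (strongly
  overlapping subunits, very low spike counts) can still collapse filters.
- At ≈ 2,000 spikes and 300 stimulus dimensions the recovery ceiling —
  measured by refitting from the ground truth itself — is a subspace
  overlap of ≈ 0.91–0.93; reported recovery numbers sit near that
  statistical limit, not far below it.
- Only 1-D bar stimuli are exercised; the design-matrix and penalty
  machinery would extend to 2-D pixel stimuli, but nothing tests it.
- No spike-history or adaptation terms; cells with strong refractoriness
  will show inflated thresholds.
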