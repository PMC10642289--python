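# Methods

## Model

`dmcflank` implements the Diffusion Model for Conflict tasks (DMC) for
flanker-type experiments.  A single Wiener process X(t) accumulates response
evidence toward a correct boundary +b or an error boundary −b, with drift that
superimposes two inputs:

- a **controlled (target) process** with constant drift rate μ_t
  (evidence/ms), and
- an **automatic (distractor) process** whose expected activation is a
  rescaled gamma density

      E[X_d](t) = A · exp(−t/τ) · (t·e / ((a−1)·τ))^(a−1),

  rising to a single maximum A at t_peak = (a−1)·τ and decaying to zero.
  Its time derivative, E[X_d](t)·((a−1)/t − 1/τ), is the distractor's
  drift-rate contribution: toward the correct boundary on congruent trials,
  sign-flipped on incongruent trials.

The response time is the boundary first-passage time plus a normally
distributed residual (nondecision) time with mean μ_r and SD σ_r.  Starting
points are drawn from a symmetric beta(α_s, α_s) distribution rescaled to
(−b, b).  Following convention for this model family, σ = 4 (diffusion
constant per √ms), α_s = 3 and a = 2 are treated as fixed; for a = 2 the
peak-time identity reduces to t_peak = τ, so τ is directly interpretable as
the distractor's peak latency in ms.

A lower μ_t makes decisions slower, leaving the late-peaking distractor
(τ ≈ 250 ms) more time to act before absorption, so a pure target-attenuation
change enlarges the mean congruency effect (CE) — the mechanism the model
ladder is designed to detect.

## Simulation

Euler–Maruyama with step dt (default 1 ms):

    X(t+dt) = X(t) + [μ_t + sign · dE[X_d]/dt] · dt + σ·√dt·ε.

The per-step distractor drift is evaluated at step midpoints (k+0.5)·dt; the
left endpoint would place the first step at t = 0, outside the activation's
domain, and the midpoint rule halves the discretization error at no cost.
Decision walks run to t_max_decision (default 5000 ms); unabsorbed walks are
flagged `nonresponse` with RT = NaN rather than forced to a boundary,
mirroring the behavioral deadline's "too slow" category.  Negative residual
draws are redrawn (with μ_r ≈ 400 ms and σ_r ≤ 50 ms the truncation effect is
negligible).  Total RTs above the 2000 ms deadline are flagged `too_slow`,
below the 150 ms floor `too_fast`; only `ok` trials enter analyses, and choice
errors are additionally excluded from RT (but not accuracy) analyses.

The inner walk is numba-compiled with block-drawn normal increments
(~10 ms per 2000-trial cell on one CPU), which is what makes
simulation-based fitting tractable in this package.

## Fitting

Observed data per condition are reduced, separately for congruent and
incongruent trials, to

- the correct-RT CDF at the five percentiles (.1, .3, .5, .7, .9), giving six
  bins with observed counts, and
- the conditional accuracy function (CAF) over five equal-count RT bins cut
  at the included-trial RT quintiles (correct and error trials together).

A candidate parameter set is scored by simulating trials under the identical
deadline/floor handling and computing

    G² = 2 Σ_congruency [ Σ₆ Oᵢ ln(p_obs,i / p_pred,i)
                         + Σ₅ n_b (pc ln(pc/p̂c) + (1−pc) ln((1−pc)/(1−p̂c))) ],

with predicted proportions obtained by binning the simulated trials at the
*observed* percentile cuts and CAF edges, clipped to [1e−10, 1−1e−10].  G² is
zero iff the predicted summaries coincide with the observed ones; all
quantiles are type-7 (linear interpolation) throughout the package.

Estimation uses differential evolution (best/1/bin, recombination 0.9,
dithered mutation (0.5, 1)) jointly over the two object conditions: boundary
b and the residual parameters (μ_r, σ_r) always take one shared value, and
each conflict parameter (μ_t, A, τ) is shared or condition-specific according
to the model specification.  Bounds: μ_t ∈ [0.1, 1.5], A ∈ [0, 40],
τ ∈ [1, 500] ms, b ∈ [20, 100], μ_r ∈ [200, 500] ms, σ_r ∈ [5, 50] ms.  The
search stops when the best G² has not improved by at least 1% over the last
50 generations (window configurable), or at the generation cap.

### Noise control

A freshly resimulated objective is extremely noisy: at 2,000 simulated trials
per cell against 10,000-trial observed summaries the G² evaluation noise has
an SD of several hundred, while the G² curvature along τ over a ±25% range is
~10 units — plain DE then chases lucky evaluations and the weakly identified
parameters (A, τ) drift.  Two remedies are built in:

1. **Common random numbers** (`DEOptions.common_random_numbers`): noise pools
   indexed by (trial, step) are generated once per fit, so every candidate is
   scored against the same randomness and the objective is a smooth function
   of the parameters.  Naively fixing the RNG seed does *not* achieve this,
   because draw consumption is path-dependent; the pools make it
   path-independent (trials outliving the 2048-step pool horizon fall back to
   fresh draws, a vanishing fraction at these drifts).  Off by default, on in
   all recovery/ladder runs in this repository.
2. **Two-phase search with stage averaging** (`DEOptions.refine_iters`,
   `DEOptions.refine_stages`): the leading generations run at the small
   search budget (2,000 simulated trials per cell); the trailing generations
   re-score the surviving population at the final-evaluation budget (10,000),
   split into a few stages with the noise pool refreshed between stages.  The
   reported optimum is the average of the per-stage bests: each stage settles
   on the optimum of one noise realization, and averaging over realizations
   shrinks the ~±25% single-realization scatter of the weakly identified
   parameters (A, τ) to roughly ±15%.  The generation cap applies to all
   phases combined.

Reported per-condition G² values are always re-evaluated at the
final-evaluation budget with fresh noise.

### Model ladder and BIC

Eight models — every subset of {μ_t, A, τ} free across the two object
conditions — are fitted per participant; the estimated-parameter count is
k = 6 + |free|.  Per condition, BIC = G² + k·ln(N) with N the included trials
entering that condition's summary, and models are ranked by the mean BIC over
the two conditions.  Counting only the parameters "governing" a condition
would give every model k = 6 and erase the complexity penalty, so the model's
full estimated-parameter count is used in each condition's penalty; this
bookkeeping is a package convention, exercised and pinned by the tests.

Parameter recovery (`recovery_study`) simulates from known values, refits the
generating specification, and reports per-parameter bias and RMSE.  At the
published group-level generating values (10,000 generating trials per cell,
search budget as above, ≤150 generations) recovery is within a few percent
for μ_t, b and μ_r and within ~25% for A and τ — consistent with the known
ordering that the conflict-strength and timing parameters are the hardest to
recover.

## Distributional analyses

RT delta functions: the nine deciles (.1 … .9) of correct-trial RT per
congruency; delta = RT_incongruent − RT_decile_congruent against the decile
midpoint RT.  A line is fitted by OLS to the nine (midpoint, delta) points
after centering the abscissa on the participant's mean correct RT over the
two congruency cells entering the function (option: grand mean over all
cells), so the intercept is the predicted CE at that mean RT and the slope
carries the distractor-timing interpretation.  PC delta functions and CAFs
use five equal-count bins, each congruency binned by its own quintiles
(pooled binning available via the `bin_edges` argument).

## Behavioral statistics

Cell summaries (mean correct RT, PC over all included trials), congruency
effects (CE_RT = incongruent − congruent; CE_PC = congruent − incongruent),
two-sided paired t with Cohen's d_z (zero-variance differences raise an
explicit error), and a repeated-measures ANOVA for balanced fully
within-subject designs.  The ANOVA computes each effect's SS by Möbius
inversion over marginal means and tests it against its interaction with the
subject factor; partial η² = SS_effect/(SS_effect+SS_error).  The array core
is vectorized over replicate datasets, which is how the type-I calibration
tests run 10⁴ null ANOVAs in under a second; it is cross-checked against
statsmodels' AnovaRM.  All design factors in the emulated studies have two
levels, where these F tests are exact, so no sphericity correction is
implemented (documented limitation for >2-level factors).  Within-subject
SEs use participant-mean centering with the √(C/(C−1)) bias correction.

## Synthetic cohorts

`StudyDesign` encodes the within-subject design (congruency × object
membership, optionally × proximity; default 40 participants, 112 trials per
cell, 2000 ms deadline, 150 ms floor).  `PopulationSpec` holds group-mean
DMC parameters per condition; the factory defaults are the published
group-level values of the μ_t-only model — experiment 1: μ_t 0.58 (same) vs
0.62 (different), A = 13.8, τ = 249, b = 74.5, μ_r = 408, σ_r = 38;
experiment 2: μ_t 0.58 vs 0.64, A = 17.8, τ = 254, b = 72.8, μ_r = 413,
σ_r = 38.

Participant heterogeneity: one standardized deviation per parameter per
participant, scaled by CV × grand mean (CV default 0.15) and applied to the
parameter's group mean in *every* condition, with rejection sampling into the
fitting bounds.  The condition effect is therefore fixed at the group level
and participant offsets cancel in within-subject contrasts — the structure a
within-subject design presumes.  A contaminant ("fast guess") rate replaces
trials with uniform-RT, chance-accuracy responses; the factory default of
0.025 was calibrated once so that default cohorts land at ~3.5–4% choice
errors (the empirical regime is ~5%), with mean RTs ~500–570 ms and PCs
94–97%.

What the generator does **not** emulate: stimulus-level structure (line
types, display geometry), block order and practice effects, response-key
mappings, sequential (post-error / congruency-sequence) dependencies, RT
autocorrelation, and any participant-level correlation structure beyond the
single shared deviation per parameter.  Passing tests therefore certify the
pipeline's behavior under the model's own data-generating process, not its
adequacy for any particular empirical dataset.

## Problem sizes and statistical design of the checks

Chosen so the full suite runs on one CPU in well under half an hour:

- Recovery checks: 10,000 generating trials per cell; DE with population
  8×dim, ≤150 generations (60 search generations, then three 30-generation
  refinement stages at the 10,000-trial budget).
- Ladder checks: 5 replicate synthetic participants, 500 observed trials per
  cell, search at 1,000 / refinement at 4,000 simulated trials per cell,
  population 5×dim, ≤40 generations.  The replicates use a μ_t-only contrast
  of 0.50 vs 0.65: at the published group-mean contrast (0.58 vs 0.62) the
  per-participant BIC margin between the top models is below one unit (as in
  the original mean-BIC table, where neighboring models differ by ~1), so a
  scaled-down selection test needs an effect the data can resolve.  Majority
  criterion: the generating model wins ≥60% of replicates.
- Delta-shift dissociation: five replicate 40-participant cohorts, 448 trials
  per cell, the same 0.50/0.65 contrast.  The model-implied intercept shift at
  the published contrast is only ~3 ms against ~15 ms participant-level
  noise, far below single-cohort significance; the dissociation (intercepts
  move, slopes do not) is the property under test, not the published effect
  size.
- Direction checks: the same-object > different-object CE ordering is
  resolved at the generating group means with 10⁵-trial simulation (the
  implied modulation, ~3–4 ms, is below the ~4 ms SE of one default cohort);
  cohort-level checks assert the robustly positive CE, fast errors, and the
  declining PC delta.
- Calibration: 10⁴ null replicates for paired t and for each ANOVA effect;
  rejection rates must be within 0.05 ± 0.01.

## Known limitations

- Simulation-based G² estimation: estimates inherit a realization bias from
  the finite final-evaluation pool; A and τ remain the least precise
  parameters (~±25% at these budgets).
- The per-condition BIC bookkeeping under parameter sharing is a convention;
  alternatives (e.g. joint BIC over both conditions) would shift all models
  equally in the μ_t-ladder but could reorder mixed cases.
- No closed-form first-passage densities, no time-varying target drift, no
  hierarchical/Bayesian estimation.
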