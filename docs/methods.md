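# Methods

## Model

Momentary fatigue on trial *t* is the sum of a fixed baseline and two latent
components, `F(t) = F_start + RF(t) + UF(t)`.  Both components start at 0
and are updated once per trial, in trial order:

* unrecoverable fatigue accumulates with the trial's force output,
  `UF(t) = UF(t−1) + θ·E(t)`, and never decreases;
* recoverable fatigue gains `α·E(t)` and loses `δ·T_rest(t)` on the same
  trial, clamped at zero: `RF(t) = max(0, RF(t−1) + α·E(t) − δ·T_rest(t))`.
  The clamp is part of the model (a recovered-to-floor state), not a fitting
  device.

`E(t)` is the trapezoidal area under the trial's force-time curve (force in
fraction-of-MVC units), divided by the participant's maximum area over all
their trials and multiplied by 10, so `E ∈ [0, 10]` and rest trials carry
`E = 0`.  `T_rest` is 7.5 s on rest trials and 2.5 s on work trials (the
non-exertion portion of a work trial); on work trials both the gain and the
decay apply before clamping.

Two readouts map the state to a rating prediction.  The fatigue readout
(0–100 scale) predicts the rating as `F(t)` itself.  The effort readout
(0–20 scale) predicts `PE(t) = (γ + F(t))·E(t)` on work trials and exactly 0
on rest trials; an additive family replaces the product with
`γ·E(t) + F(t)`.  `F_start` is the participant's pre-task fatigue rating, or
0.01 when that rating is zero or was never collected (effort-rating
experiments collect none).  Predictions are deliberately *not* clamped to
the rating-scale bounds; scale saturation is treated as a property of the
data, not the model.

The candidate family comprises nested restrictions: a static null model
(γ only; effort readout only), UF-only (θ), RF-only (α, δ), one-parameter RF
(α, with the decay tied as δ = α so a single parameter scales both effects),
UF plus one-parameter RF (θ, α tied), and the full model (α, δ, θ).
Fatigue-readout models have no γ, giving five models; effort-readout models
add γ, giving six, or six more in the additive family.

### Prediction timing

Ratings are collected after the trial's exertion and outcome, so the
prediction for trial *t* uses the state *after* trial *t*'s update by
default.  Because the alternative is defensible, the pre-update convention
is implemented behind the `state_timing="pre"` switch; all defaults,
results and tests use `post`.

### Failed trials

Failed work trials stay in the trajectory and in the residuals with their
actually produced force (the model consumes what was exerted, not what was
requested).  `include_failed=False` excludes them from the residuals only —
their exertion always drives the latent dynamics.

## Fitting

Per participant and model, parameters minimise the residual sum of squares
over rated trials.  The search is Nelder–Mead (derivative-free simplex)
restarted from a full factorial grid of six equally spaced values on [0, 1]
per free parameter (6^d starts); the lowest-RSS solution wins, first-in-grid
order breaking exact ties.  Non-negativity is enforced by returning a large
finite penalty (10¹²) for any negative parameter, which keeps the
unconstrained simplex inside the feasible region without reparameterisation
bias.  Default per-start tolerances are 1e−4 on both simplex size and
function spread with at most 200·d iterations, mirroring the common
derivative-free defaults; noise-free validation runs tighten these
(xatol 1e−8, fatol 1e−12, 400·d, two polish restarts from the incumbent)
because a ~1e−4 parameter error already produces visible residuals over 120
trials.  Fits are deterministic given data and settings.

Fits are scored with `AIC = n·ln(RSS/n) + 2d`, where *n* counts the trials
contributing residuals.  A zero RSS (possible on noise-free data) is
log-degenerate; the fitting path floors it at 1e−12 with a warning.  `R²`
is the squared Pearson correlation between observed and predicted ratings,
reported as missing when either side has zero variance.

The fitting core is exposed as a scikit-learn-style estimator
(`FatigueRatingModel`), so model variants compose with sklearn's `clone`,
`get_params`/`set_params` and pipeline tooling; `fit_participant` and
`fit_cohort` are thin functional wrappers.

### Closed-form trajectory evaluation

The clamped RF recursion has the exact closed form
`RF(t) = C(t) − min(0, min_{s≤t} C(s))` with `C = cumsum(α·E − δ·T_rest)`,
which allows a loop-free vectorised trajectory (a running minimum instead of
a per-trial branch).  The equivalence with the literal per-trial update is
property-tested.

## Group-level comparison

Per-subject AICs are converted to approximate log model evidences as
−AIC/2.  Random-effects Bayesian model selection then iterates the standard
variational fixed point — subject-wise responsibilities
`u ∝ exp(log evidence + ψ(α_k) − ψ(Σα))`, normalised per subject and summed
into Dirichlet counts `α_k = prior + Σ u` — to convergence (default prior
mass 1 per model, tolerance 1e−6 on α).  Responsibilities are computed in
log space with per-row max subtraction, so evidence spreads of 1e4 log-units
do not overflow.  Exceedance probabilities (the posterior probability that
each model is the most frequent in the population) are estimated from 10⁶
seeded Dirichlet draws by default; for two models the Beta-integral
quadrature `P(Beta(α₁, α₂) > ½)` serves as an independent oracle in the
tests.  Summed AICs and per-model best-fit counts (by AIC and by RSS, ties
to the lowest model index, logged) complete the report.

## Synthetic experiments

The generator emulates the grip-force rating task: 120 trials, the 12
effort-level × reward combinations (0/30/39/48 % MVC × 6/8/10 credits)
shuffled independently within each consecutive block of 12 so every
combination appears exactly once per block ("blocked" counterbalancing — the
even-distribution intent, since the original shuffling algorithm is
unspecified); one shared sequence across simulated participants by default.
Work-trial force traces follow a ramp-and-hold template (0.5-s ramp, hold at
8 % above target, Gaussian wobble, optional extra force per credit when the
reward is visible — the reward-vigour effect; hidden rewards, as when reward
is revealed only after exertion, produce none), with a configurable
probability of holding less than the required 3 s (a failed trial).  Ratings
are the model prediction from known ground-truth parameters plus Gaussian
noise, rounded to integers and censored to the scale — both switchable for
exact-recovery diagnostics.  An optional `max_step` emulates the
rating-scale carry-over (the cursor starts at the previous response and
moves a bounded number of increments); it is off by default because no
adjustment-speed measurement exists to calibrate it.  Sequence, force and
rating noise draw from separate named streams under one master seed, so a
cohort is byte-reproducible and each noise source can be varied alone.

### Recovery-study conditions

Parameter-recovery and model-recovery simulations use `recovery_config()`:
fatigue readout, baselines uniform on 5–30, rating noise 5 units (5 % of
the scale), and ground-truth draws α ~ U(0.1, 1.6), δ/α ~ U(1.7, 2.4),
θ ~ U(0.01, 0.06).  Two structural facts dictate this region:

1. **α–θ confounding.**  If RF never reaches its zero clamp, the trajectory
   depends only on α + θ and δ, so α and θ are not separately identifiable.
   With δ above ≈1.6·α the net RF drift per 12-trial block is negative, the
   clamp binds every block, and the confound is broken.
2. **Scale realism.**  The supports keep trajectories on the 0–100 scale
   for typical baselines (UF ends below ~45, RF excursions below ~20), so
   ceiling censoring is rare, as in the task being emulated.

The amplitude range reflects a design power analysis: at noise 5 the
least-squares (α, δ) estimate scatters along a ridge (within work runs,
cumulative exertion and cumulative rest time are nearly collinear), so the
true parameter spread must dominate that scatter for recovery correlations
to be meaningful.  δ remains the hardest parameter: once rests fully reset
RF, the rest-trial dip saturates at RF itself and δ is identified mainly
through the effort-level contrast within work runs.  Across 50-subject
cohorts its true-vs-recovered correlation averages ≈0.83 ± 0.05 — honestly
marginal against a 0.8 benchmark, and an intrinsic limit of this design at
this noise level, not an optimizer artefact (fits reach or beat the RSS of
the generating parameters in all checks).

What passing recovery tests do *not* show about real data: real rating
noise need not be Gaussian or trial-independent, real parameters need not
fall in the identifiable region (a real participant whose RF never clears
zero is indistinguishable from one with a larger θ), and the carry-over and
anchoring behaviour of a physical rating scale is not modelled.

## Validation problem sizes

The test suite validates noiseless recovery on 20 simulated subjects, noisy
recovery on 50, and model recovery on two 40-subject cohorts (generated
under the full and the UF-only model).  `scripts/acceptance.py` re-runs the
same computations at reduced sizes (8 / 30 / 20 subjects) chosen so a
single-CPU run completes in a few minutes; sizes accompany every reported
number.

## Known limitations

* Model evidence is approximated by −AIC/2; protected exceedance
  probabilities and Bayesian omnibus risk are out of scope.
* Effort enters linearly everywhere (the task uses only low-to-moderate
  levels); no nonlinear effort-cost transform is provided.
* Reward never enters the rating model itself — its only modelled influence
  is on force production in the simulator.
* The blocked counterbalancing is a stand-in for the original (unspecified)
  sequence-generation procedure.
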