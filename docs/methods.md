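# Methods

## Model

The package models disease course through a latent 5-vector
x(t) = [x_tau, x_abeta, x_lang, x_mem, x_praxis] whose rate of change is an
affine function of its current value and two baseline covariates,

    dx/dt = (V + y_age W_age + y_apoe W_apoe) x + v0,

with y_age the baseline age standardised by (age − 75)/10 and y_apoe a 0/1
APOE ε4 carrier indicator.  The only subject-level parameter is the initial
state x0^s; the velocity field is shared by the population.  The key
structural assumption is the block-triangular form of V, W_age and W_apoe:
the CSF rows (tau, abeta) have zero coefficients on the cognitive columns,
so biomarker dynamics are independent of cognitive status while cognition
responds to the biomarkers.  The canonical index order is
(tau, abeta, lang, mem, praxis); the CSF block is indices {0, 1}.

Because the field is affine with a time-constant matrix, trajectories are
exact: x(t) is read off the matrix exponential of the augmented system
[[A, b], [0, 0]] scaled by t.  This avoids inverting A (which may be
singular or near-singular once estimated) and is valid for negative t, used
for backward propagation in long-term simulations.  Age is frozen at
baseline along a trajectory; letting age advance would make A
time-dependent and forfeit the closed form, and over the 10–20-year
horizons involved the induced velocity change is second-order relative to
the field itself.  The batched exponential is a vectorised
scaling-and-squaring Padé-13 implementation, unit-tested against scipy to
~1e−13 relative error, used because a likelihood evaluation needs thousands
of small 6×6 exponentials.

### Observation layer

Each channel k is linked to its latent component by a bounded, strictly
increasing sigmoid, lower_k + (upper_k − lower_k)·logistic(slope_k·(x_k −
mid_k)), giving plateaus at both extremes of the observed scale, plus
Gaussian noise σ_k in observation units.  CSF amyloid-beta is right-censored
at the assay limit of 1700 pg/mL: a censored row contributes
log P(X > 1700) = log Φ((mean − 1700)/σ).  A configurable lower limit
exists but is off by default.  Cognitive items, when provided as raw
responses, are scored per visit into the three domain traits by a graded
response model (P(cat ≥ c) = logistic(a(θ − b_c))) with a standard-normal
prior; the trait MAP and its curvature standard error feed the dynamic
model as Gaussian pseudo-observations with variance σ² + SE².  This
two-stage treatment keeps the scoring step replaceable; a fully joint IRT
likelihood would change only the observation module.  Larger trait values
mean worse cognition, matching the orientation of ADAS-Cog scores.

Identifiability: the latent scale, the link slope/midpoint and the velocity
magnitudes trade off against one another.  The default configuration
therefore fixes all link parameters (asymptotes roughly the plausible data
range widened; slopes near 1; midpoints anchoring the healthy population)
and estimates velocities, noises and the hierarchy on the resulting latent
scale.  `ModelConfig(estimate_links=True)` frees slope and midpoint under
anchoring priors (log-normal slope around 1, normal midpoint around the
configured value) for users who accept the weaker identification; absolute
comparisons of velocity entries are only meaningful under fixed links.

### Clinical layer

The diagnosis D ∈ {CN < MCI < AD} at an assessment time is ordered-logit:
η = β_x·x(t) + β_y·y, P(CN) = logistic(c1 − η), P(CN∪MCI) =
logistic(c2 − η), with c1 < c2 enforced by parametrising the log gap.  The
predictors are the latent states, not the link-transformed observation-scale
values, and the covariates reuse the same standardisation as the dynamics.

## Priors

Weakly informative throughout, on the standardised latent scale (per-year
units for velocities): Normal(0, 0.5) on every free velocity entry and v0;
Normal(0, 5) on the population mean mu0; half-Normal(2.5) on the population
scale tau0; half-Normal(0.2·(upper_k − lower_k)) on each observation noise
σ_k, which treats pg/mL channels and dimensionless traits alike;
Normal(0, 5) on ordered-logit coefficients and the first cutpoint, with a
half-Normal(5) gap.  The velocity scale is chosen so that prior-predictive
trajectories change O(1) per decade — the slow-progression regime the model
is built for.

## Posterior computation

Sampling is blocked adaptive Metropolis-within-Gibbs on numpy, designed
around the model's structure:

* **Initial states.** All subjects' x0 are proposed and accepted in one
  vectorised sweep; given the population parameters their conditionals are
  independent, and the cached flow operators make a sweep a few
  matrix-vector products.  Per-subject step sizes and per-component
  variances adapt during warmup (target acceptance 0.28).
* **Velocity blocks.** Two blocks — (V, v0) and (W_age, W_apoe) — in an
  exactly reparametrised centred-covariate basis (covariates are centred
  within the cohort and the stored draws mapped back), which removes the
  V–W collinearity.  Each proposal is a joint "ridge-following" move: the
  per-subject x0 residuals are transported through the Gaussian conditional
  implied by a linearisation of the links (whiten under the current
  precision, unwhiten under the proposed one, with the exact Jacobian in
  the acceptance ratio), so velocity moves walk along, not across, the
  velocity/initial-state ridge.  Proposal covariances are Gauss-Newton:
  the Fisher information of the linearised pseudo-observation model with
  the initial states marginalised by Schur complement, refreshed three
  times during warmup.  The linearisation only ever shapes proposals;
  Metropolis-Hastings acceptance uses the exact joint density, so the
  chain's stationary distribution is untouched.
* **Hierarchy.** mu0 is a conjugate Gibbs draw; log tau0 a small
  random-walk block; and an interweaving (non-centred) move updates
  (mu0, tau0) with the standardised residuals z = (x0 − mu0)/tau0 held
  fixed, translating and rescaling all subjects jointly — this breaks the
  centred-parameterisation funnel that otherwise throttles the prior-mode
  and small-n regimes.
* **Noise and ordered logit.** Plain adaptive-Metropolis blocks reusing the
  cached latent states.

Warmup-only adaptation (Robbins-Monro step sizes, equal-weight covariance
learning with a floor) keeps the kept draws from a fixed kernel.  Chains run
sequentially from jittered data-informed starts (x0 seeded by
inverse-linking each subject's earliest uncensored observations).
Diagnostics (split R-hat, bulk ESS via arviz) attach to every fit; R-hat
above 1.05 raises a logged warning rather than failing, since the velocity
blocks mix at the random-walk-Metropolis limit (integrated autocorrelation
of order the block dimension) and posterior means converge long before
R-hat cosmetics do.  Production analyses should use the default 2 × (1000
warmup + 1000 draws) or more; the recovery studies below deliberately run
shorter single chains and rely on the mean/coverage checks instead.

`likelihood_weight = 0` switches the same machinery to prior sampling,
which is verified against the analytic prior marginals in the tests.

## Forecasting and conversion times

A new subject's x0 is sampled conditional on its first 2 years of
observations and diagnoses, separately for each (thinned) posterior draw
with population parameters held fixed — a short vectorised adaptive
Metropolis chain per draw, initialised at the inverse-linked earliest
observations.  Trajectories then propagate along the velocity field on a
uniform monthly grid (default; composing single-step flow operators rather
than exponentiating per time point), optionally 10 years backward and 20
forward.  Label-probability curves are per-draw ordered-logit pushforwards;
the reported curve is the draw average.  The conversion time t_p is the
first linear-interpolated crossing of the posterior-mean P(AD) curve at
p ∈ {30%, 50%, 70%}, with a 10-year horizon and an explicit beyond-horizon
flag; t50 is the point prediction and the per-draw crossing distribution is
attached for uncertainty.  Crossing times of increasing thresholds are
automatically ordered.

Velocity-field summaries condition on a region of initial-state space:
(subject, draw) pairs whose x0 draw falls inside contribute their velocity
vector, summarised per covariate stratum by the mean and 90% highest-density
interval.

## Evaluation machinery

Leave-one-site-out cross-validation refits the model on all-but-one site
and forecasts every held-out subject from its baseline window, scoring a
prediction at each diagnosis assessment after 2 years (assessment-level
pooling; the within-subject clustering caveat is recorded in the report).
Discrimination uses AUROC of P(AD) against the binarised label, computed by
the rank-sum formula (exactly concordant-pair counting with half credit for
ties), reported at 3/5/7-year horizons, pooled over all assessments, and at
last visits.  Calibration uses confidence- and classwise-reliability
diagrams at 0.2-wide bins with central 95% Beta(1,1)-Binomial posterior
intervals; the confidence diagram is restricted to probabilities above 0.4
because 1/3 is the smallest attainable maximum over three classes.
Decision curves report NB(p_th) = TP/N − FP/N·p_th/(1−p_th) for the model,
treat-all and treat-none; treat-all crosses zero exactly at the prevalence.
Conversion errors are predicted-minus-observed times (first AD diagnosis
for converters, maximum follow-up for non-converters, negative values
flagging premature predictions) with a cumulative |error| curve over
converters.  One master seed fans out per-fold seeds.

## Synthetic cohorts

The generator forward-simulates the full model and is the package's study
bed.  Defaults emulate the sampling structure of a large observational AD
cohort: ages Normal(73, 7) truncated to [55, 92]; APOE ε4 prevalence 0.45;
initial states Normal(0, 1) on the latent scale; roughly biennial CSF
visits thinned and jittered so subjects average ~1.9 CSF observations with
mean/max follow-up ≈1.5/10 years; denser cognitive testing averaging ~5.6
visits with follow-up ≈4/15 years; at most one diagnosis assessment per
year; amyloid censored at 1700 pg/mL.  The true velocity field is
illustrative, not estimated: tau accumulation accelerates with tau and with
amyloid burden, cognition declines when either CSF marker is abnormal,
carriers accumulate amyloid faster, CSF dynamics are slower than cognition.
Ground truth (parameters, x0, noiseless 0.5-probability crossing times on a
30-year horizon) is serialised next to every cohort.  Frozen-seed fixtures
(tiny 12/2, small 150/6, medium 600/12 subjects/sites) carry committed
checksums.

What the generator does not emulate: real link misspecification,
informative dropout, site batch effects, diagnosis label noise beyond the
ordered-logit model, and covariate–schedule dependence.  Passing recovery
and evaluation checks on these cohorts therefore demonstrates correctness
of the machinery under the model's own assumptions, not clinical validity
on real data.

## Study sizes and numerical choices

The recovery study uses 20 cohorts of 150 subjects with 4 regular visits
over 3 years and single chains of 500 + 500 sweeps; the leave-one-site-out
integrity study uses 144 subjects across 12 sites at 250 + 250 sweeps; the
conversion-time study uses 120 subjects per noise setting with forecasting
under the true parameters (degenerate posterior), isolating the prediction
layer from sampler noise.  These sizes were chosen so each study carries
clear statistical signal while a full run stays in the minutes range on one
core.  Other fixed choices: monthly forecast grid (assessments are at most
annual); 90% HDIs for velocity summaries; probability floors of 1e−300
before logs; trait-scoring search bounded to [−8, 8]; pseudo-observation
probabilities clipped to [1e−3, 1−1e−3] inside proposal builders (never in
the exact likelihood).

## Known limitations

* Velocity entries mix at the preconditioned random-walk limit; ESS per
  sweep is low and R-hat warnings are common at short run lengths.  A
  gradient-based sampler would dominate if the gradient of the matrix
  exponential were implemented; this is the main upgrade path.
* The two-stage IRT treatment ignores trait-estimate non-Gaussianity for
  extreme response patterns.
* Age frozen at baseline slightly misstates decade-long extrapolations for
  the W_age term.
* Assessment-level pooling in calibration and AUROC treats repeated
  assessments of a subject as independent.
* The forecast CLI subcommand refits the model deterministically from the
  recorded seed rather than deserialising joint draws; the draws file
  stores population parameters only.
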