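# Methods

## The model

`glvnet` fits generalized Lotka–Volterra (gLV) community dynamics

    dx_i/dt = (α_i + Σ_j β_ij x_j) x_i,        i = 1..N,

to species-abundance time series.  `α_i` is species i's net per-capita growth
rate (1/time); `β_ij` (1/(abundance·time)) is the per-capita influence of
species j on species i — its sign encodes the interaction type, its magnitude
the strength.  An exogenous perturbing species (an invader whose own dynamics
are not modelled) enters through a susceptibility term: `α_i` becomes
`α_i + ε_i·x_exo(t)`, with `x_exo` evaluated by monotone piecewise-cubic
interpolation of its observed series (constant extrapolation outside the
window).  Trajectories are integrated with LSODA at rtol 1e-7 / atol 1e-9;
a trajectory exceeding 1e6 times the initial scale aborts with a recoverable
`SimulationDiverged` carrying the failure time, which the optimizers use to
reject unstable trial parameterizations.

Key modelling assumptions inherited from the gLV form: additive pairwise
fitness effects, linear (unsaturated) functional responses, no higher-order
interactions, and — for relative-abundance field data — a community near
carrying capacity so that relative indices can stand in for abundances.

## Inference

Three estimators share one interface and one sign-constraint mechanism
(restrictions enforced as box bounds: positive → [0, ∞), negative → (−∞, 0],
zero → pinned).

**Gradient matching (`GLVLinearRegression`).**  The log-derivative identity
`d ln x_i/dt = α_i + Σ_j β_ij x_j` turns fitting into per-species bounded
linear least squares of estimated gradients on `[1; X]`.  Gradients come from
analytic differentiation of a natural (not-a-knot) cubic spline through the
log abundances; zeros are floored at half the species' smallest positive
value first.  Fast, but the gradient estimates — not the data — set its
accuracy ceiling: on sparsely sampled oscillations the spline derivative is
badly biased.

**Nonlinear regression (`GLVNonlinearRegression`).**  Bound-constrained
trust-region least squares (`scipy.optimize.least_squares`, TRF) on the
simulated-minus-observed residual over the coefficients, warm-started from
the constrained linear fit by default.  Diverging trial simulations return a
large finite residual so the trust region contracts instead of crashing.

**Latent gradient regression (`LatentGradientRegression`).**  The same
simulation residual, but optimized over the N×M latent gradient matrix `g`.
Each evaluation maps `g` to coefficients through the inner constrained linear
regression, simulates, and adds the ridge penalty
`J = λ_α Σ α_i² + λ_β Σ_{i≠j} β_ij²` (self-limitation deliberately
unpenalized: near carrying capacity, strong intraspecific competition is
expected).  `g` is updated by a Levenberg–Marquardt-style trust-region step;
the initial `g` is the spline estimate, so the procedure refines the
gradients that gradient matching would have taken as fixed.  The Jacobian
with respect to `g` factors through the coefficients: ∂X̂/∂θ by forward
finite differences (relative step 1e-6; one simulation per locally varying
coefficient) times ∂θ/∂g computed analytically from the inner regression's
active set (coefficients at a bound contribute zero rows).  This keeps each
iteration at O(N²) simulations instead of O(N·M).  Stopping: relative
objective change below 1e-8 or 100 iterations; an initialization whose
objective is already at machine zero returns immediately.  The accepted-step
objective trace is non-increasing by construction.

Penalty weights are selected by the leave-middle-out rule: fit on the series
with the middle observation removed, score the summed squared error at the
held-out time, take the grid minimizer, refit on everything.  With dense data
relative to parameters, (0, 0) is the expected winner.

**Adjusted R².**  Never standardized in the field, so fixed here: pooled
R² = 1 − SSE/SST with SST about each species' own mean, adjusted as
1 − (1 − R²)(n − 1)/(n − p − 1), n = N·M, p = number of coefficients not
pinned to zero.  Parameter recovery is summarized the same way from the
ordinary regression line of estimated on true coefficients (p = 1).

## Prior knowledge: food web → sign constraints

Species are classified into three tiers (resource prey, meso predator, top
predator) subject to (a) trophic-index ordering between tiers and (b) every
documented predator strictly above its prey.  Tiers are contiguous blocks of
the index-sorted species list (ties broken prey-first by a local topological
sort); among feasible splits the deterministic tie-break keeps species as low
as possible.  The summary web then contains: predation for adjacent-tier
pairs and for documented pairs at any tier gap, competition within a tier,
self-limitation everywhere, and no interaction otherwise.  Conversion to
signs: predation (j eats i) → β_ij < 0, β_ji > 0; competition → both
negative; none → both zero; growth positive only on the bottom tier.  When
one species is declared exogenous it leaves the matrix and its web links
become susceptibility signs instead.  "Immediate lower level" is read
literally: top predators do not automatically eat the bottom tier — only a
documented pair adds that link.

## Preprocessing

Multi-gear catch-per-unit-effort counts are standardized within gear and
time (shares summing to one across species) and summed over gears; a
gear-time column with zero total is skipped with a warning, not an error.
Denoising is classical EMD — cubic-spline envelope sifting with
mirror-extended extrema, Cauchy stop criterion 0.2, at most 10 sifting
passes — followed by Hurst filtering: IMFs whose rescaled-range Hurst
exponent (log-spaced windows ≥ 8 samples) falls below 0.5 are treated as
anti-persistent noise and dropped; the rest plus the residual trend rebuild
the series, clipped at zero.  Caveat observed on the synthetic benchmark:
with ~20 samples, a genuine oscillation can decompose into an IMF with
Hurst just below 0.5 and be removed, so short, weakly noisy series are
better fit raw; smoothing pays off when the noise amplitude is substantial
relative to the signal.

## Uncertainty

**Ensembles.**  Each of n candidates multiplies every nonzero coefficient's
magnitude by a log-normal factor (log-sd σ; signs reattached, pinned zeros
untouched), is re-optimized by the nonlinear estimator, and is kept if its
sMAPE — `(1/NM) Σ |x − x̂|/(|x| + |x̂|)`, 0/0 terms counting zero — stays
below a cutoff.  The cutoff is a config choice made by inspecting the full
sMAPE sample (preserved in every report); defaults follow the field analysis
this package is built around: σ = 0.2, cutoff 0.25, same ridge weights as
the original fit.  Ensemble summaries: coefficient of variation
(sample sd / |mean|; undefined, reported as missing, when the mean is 0) and
forecasts (member simulations from the last observation; pointwise mean and
sd; diverging members excluded and counted).

**Confidence scores.**  For each free coefficient, the score is 1 − p of the
two-sided t-test that it is zero, with standard errors from the
finite-difference trajectory Jacobian: se = s·√[(JᵀJ)⁻¹]_pp,
s = ‖X − X̂‖_F/√df, df = N·M − (free coefficients).  Sign-pinned zeros are
excluded from df and scored 0; coefficients the trajectories are insensitive
to (singular JᵀJ) are scored 0 explicitly.  Averaging scores across an
ensemble is the package's conservative evidence summary.  Scores are raw
1 − p values; no multiplicity correction is applied, and that is deliberate —
they rank evidence, they are not family-wise error rates.

**Susceptibility.**  With (α, β) frozen at an ensemble member's values, each
ε_i is fit one at a time (all other ε_j = 0) by bounded scalar least squares
and scored with df counting one parameter.  One-at-a-time fitting avoids the
overfitting of a joint ε fit but is only consistent when interspecific
feedback is weak; with strongly coupled communities an omitted true ε_j
leaks into ε̂_i.  The recovery study therefore uses a weakly coupled
community.  An identically zero exogenous series leaves every ε
unidentifiable: returned as 0 with score 0.

## Synthetic data

The 3-species benchmark uses a fixed observation design — x0 =
(0.15, 0.6, 0.4), samples every 5 time units on [0, 100] (21 points),
per-species diffusion 0.001 — with fixture coefficient magnitudes
α = (0.66, 0.45, −0.54), β = ((−0.31, −0.10, −2.26), (−0.21, −0.90, −1.14),
(1.84, 1.14, −0.08)): one predator on two competing prey, all species
self-limiting, giving bounded positive trajectories with a slowly damped
oscillation (period ≈ 12) that the 5-unit sampling barely resolves.  That
regime is the point: spline gradients are systematically wrong there, so
gradient matching underfits while the latent-gradient search recovers the
system.  Environmental noise follows dX_i = (α_i + Σβ_ij X_j)X_i dt +
σ_i dW_i — additive diffusion — integrated by Euler–Maruyama with internal
step 0.002 and states clipped at zero.  The additive noise term means the
noise level is absolute, not proportional to abundance.

Random communities (`make_community_spec`) draw sign-feasible coefficients
from a generated trophic prior: dominant self-limitation (U(0.5, 1.0)),
interaction magnitudes floored half-normals (predation 0.25 + |N(0, 0.6)|,
competition 0.15 + |N(0, 0.2)| — links too weak to shape dynamics are not
meaningful interactions), and rejection sampling until trajectories are
bounded, all species persist, and at least half the species fluctuate
non-monotonically over the window.  The default design samples every 1 time
unit over a horizon of 30 so the informative transient is resolved.  What
these generators do *not* emulate: observation (counting) noise, missing
years, gear selectivity drift, age structure, or environmental covariates —
so passing tests demonstrate correctness of the machinery under the model's
own assumptions, not robustness to every pathology of field data.

Even so, single short trajectories genuinely underdetermine these systems:
in the end-to-end study roughly one in five truly nonzero couplings is
driven to its zero bound while the fit R² stays near 1.  This is a property
of the data, not the optimizer (gradient matching shows the same), and it is
why the surrounding methodology leans on ensembles and confidence scores
rather than any single best fit.

## Study designs behind the reported numbers

* Noise-free benchmark: all three methods on the deterministic benchmark;
  fit and recovery adjusted R² (63 data values, 12 free coefficients).
* Noisy benchmark: 50 stochastic replicates; median fit adjusted R² per
  method.  Note: with a trust-region solver warm-started from the
  constrained linear fit, plain nonlinear regression is statistically
  indistinguishable from the latent-gradient search on this benchmark; the
  robust, reproducible ordering is both simulation-based methods far above
  gradient matching.
* Coverage: single-species logistic (α = 1, β = −1, x0 = 0.1, 25 samples on
  [0, 10]), iid N(0, 0.02) observation noise, 100 replicates.  The fit
  conditions on the first observation, so that sample is generated
  noise-free; intervals are the 95% t-intervals above.
* Separation: predator–prey pair plus an uncoupled bystander whose link to
  the prey is allowed by the constraints but absent in truth; 20 noise
  seeds, 6-member ensembles (σ = 0.2, cutoff 0.5); success = mean score of
  the true link exceeds the null link's.
* Determinism: every stochastic routine re-run with the same seed must
  reproduce byte-identical arrays.

All study sizes (50 replicates, 100 intervals, 20 seeds, 6 members) are the
package's chosen designs, balancing Monte-Carlo error against the cost of
repeated ODE fits.

## Known limitations

* LGR is local: it inherits its basin from the spline initialization, and a
  better fit is not always closer to the truth.
* The t-based intervals assume iid Gaussian residuals and a locally linear
  model; with process (rather than observation) noise they are heuristic.
* The three-tier web is fixed; deeper hierarchies are out of scope.
* Relative-abundance data identify parameters only up to the
  carrying-capacity convention discussed above.
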