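# glvnet

Ecological network inference for generalized Lotka–Volterra (gLV) community
models.  Built for the situation ecologists actually face — short, noisy,
annually sampled abundance series from field monitoring programs — where the
standard gradient-matching approach to gLV fitting breaks down.

The gLV model couples species growth and pairwise interactions:

    dx_i/dt = (α_i + Σ_j β_ij x_j) x_i

`α_i` is species i's per-capita net growth rate and `β_ij` the effect of
species j on i (sign = interaction type, magnitude = strength).  `glvnet`
estimates (α, β) from a species × time abundance matrix with:

* **Latent gradient regression (LGR)** — instead of regressing error-prone
  numerical derivatives on the data (classical linear-regression fitting),
  the log-abundance time-derivatives are treated as latent variables and
  optimized so the *simulated* trajectories match the observations; the
  coefficients follow from an inner sign-constrained linear regression at
  every step.
* **Food-web sign constraints** — a three-tier summary food web built from
  trophic indices and documented predator–prey pairs pins the sign of every
  coefficient (predation, competition, self-limitation, non-interaction),
  so the search space shrinks and the inferred network can never contradict
  prior knowledge.
* **Perturbation ensembles** — the best fit is perturbed log-normally and
  re-optimized many times; candidates with symmetric mean absolute
  percentage error (sMAPE) under a cutoff form an ensemble whose spread
  measures how well the data constrain each coefficient (coefficient of
  variation, forecasts with uncertainty bands).
* **Confidence scores** — per-coefficient scores 1 − p from t-based
  nonlinear-regression intervals, averaged over the ensemble; plus
  one-at-a-time susceptibility fits quantifying the impact of an exogenous
  (e.g. invasive) species.

Preprocessing utilities cover multi-gear catch-per-unit-effort
standardization, denoising by empirical mode decomposition with
Hurst-exponent filtering, and spline gradient estimation.

Estimators follow scikit-learn conventions (`fit`, `predict`, `score`,
`get_params`); a `typer` CLI (`glvnet simulate|standardize|smooth|
constraints|infer|ensemble|confidence|susceptibility|forecast|run`) chains
the stages for shell use.

## Worked example

Fit the built-in 3-species benchmark community (one predator, two competing
prey; 21 samples at interval 5) three ways and compare:

```python
import numpy as np
from glvnet import (
    GLVLinearRegression, fit_lgr, make_benchmark_spec,
    parameter_recovery_adjusted_r2,
)

spec, constraints = make_benchmark_spec()
x = spec.simulate_deterministic()          # species x time AbundanceSeries

lr = GLVLinearRegression(constraints=constraints).fit(x)
lgr = fit_lgr(x, constraints=constraints)

print(f"gradient matching  fit adj R^2: {lr.adjusted_r2_:.3f}")
print(f"latent gradients   fit adj R^2: {lgr.adjusted_r2:.3f}")
print(f"parameter recovery adj R^2:     "
      f"{parameter_recovery_adjusted_r2(spec.truth, lgr.params):.3f}")
print("estimated growth rates:", np.round(lgr.params.alpha, 3))
```

Output:

```
gradient matching  fit adj R^2: 0.689
latent gradients   fit adj R^2: 1.000
parameter recovery adj R^2:     1.000
estimated growth rates: [ 0.66  0.45 -0.54]
```

The sparse sampling undersamples the community's oscillation, so spline
derivatives mislead the classical linear regression (adjusted R² 0.69),
while the latent-gradient search reconstructs both the dynamics and the true
coefficients (α_true = (0.66, 0.45, −0.54)) essentially exactly.  Building
an ensemble and scoring confidence continues from the fit:

```python
from glvnet import build_ensemble, ensemble_confidence

ens = build_ensemble(x, lgr, n=50, sigma=0.2, cutoff=0.25,
                     constraints=constraints, seed=0)
report = ensemble_confidence(ens, x, constraints=constraints)
print(report.to_frame().head())
```

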