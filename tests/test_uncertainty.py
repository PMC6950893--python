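"""Adjusted R^2 arithmetic, t-based confidence scores, CV and susceptibility."""

import numpy as np
import pytest

from glvnet import (
    AbundanceSeries, ExogenousSeries, GLVParameters, SignConstraintSet,
    adjusted_r2, ensemble_confidence, fit_susceptibility, parameter_confidence,
    parameter_cv, simulate_glv, simulate_glv_exogenous,
)
from glvnet.ensemble import Ensemble, EnsembleMember
from glvnet.uncertainty import _t_scores


def toy_ensemble(param_list):
    members = tuple(
        EnsembleMember(params=p, smape=0.0, adjusted_r2=1.0, provenance=i)
        for i, p in enumerate(param_list)
    )
    return Ensemble(members=members, cutoff=1.0,
                    all_smape=np.zeros(len(members)), n_rejected=0)


class TestAdjustedR2:
    def test_perfect_prediction(self, rng):
        x = rng.uniform(0.1, 1.0, (2, 6))
        assert adjusted_r2(x, x, 3) == pytest.approx(1.0)

    def test_null_predictor_non_positive(self, rng):
        x = rng.uniform(0.1, 1.0, (2, 6))
        xhat = np.repeat(x.mean(axis=1, keepdims=True), 6, axis=1)
        assert adjusted_r2(x, xhat, 0) <= 0.0

    def test_hand_computed_toy_matrix(self):
        """2x3 matrix checked against spreadsheet-style arithmetic."""
        x = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
        xhat = np.array([[1.1, 1.9, 3.2], [2.1, 1.9, 2.0]])
        sse = 0.01 + 0.01 + 0.04 + 0.01 + 0.01 + 0.0
        sst = 1.0 + 0.0 + 1.0 + 0.0 + 0.0 + 0.0
        r2 = 1.0 - sse / sst
        expected = 1.0 - (1.0 - r2) * (6 - 1) / (6 - 1 - 1)
        assert adjusted_r2(x, xhat, 1) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_signalled(self):
        x = np.full((1, 5), 2.0)
        with pytest.raises(ValueError):
            adjusted_r2(x, x, 0)


class TestParameterConfidence:
    def test_noise_free_self_data_scores_one(self, benchmark, benchmark_series):
        spec, cons = benchmark
        report = parameter_confidence(spec.truth, benchmark_series,
                                      constraints=cons)
        assert np.all(report.alpha_score > 0.999)
        nz = spec.truth.beta != 0.0
        assert np.all(report.beta_score[nz] > 0.999)

    def test_constrained_zero_excluded_and_scored_zero(self, benchmark, benchmark_series):
        spec, cons = benchmark
        pinned_signs = cons.beta_sign.copy()
        pinned_signs[0, 1] = "zero"
        pinned = SignConstraintSet(alpha_sign=cons.alpha_sign.copy(),
                                   beta_sign=pinned_signs)
        beta = spec.truth.beta.copy()
        beta[0, 1] = 0.0
        params = GLVParameters(alpha=spec.truth.alpha.copy(), beta=beta)
        full = parameter_confidence(params, benchmark_series, constraints=cons)
        reduced = parameter_confidence(params, benchmark_series, constraints=pinned)
        assert reduced.beta_score[0, 1] == 0.0
        assert reduced.df == full.df + 1

    def test_score_monotone_in_magnitude(self):
        ses = np.ones(4)
        scores = _t_scores(np.array([0.0, 0.5, 1.0, 5.0]), ses, df=10)
        assert np.all(np.diff(scores) > 0)

    def test_scores_track_coefficient_magnitude(self, benchmark, benchmark_series):
        """Confidence rises with |coefficient| (rank correlation > 0)."""
        from scipy.stats import spearmanr

        spec, cons = benchmark
        report = parameter_confidence(spec.truth, benchmark_series,
                                      constraints=cons)
        noisy = benchmark_series.with_values(
            np.clip(benchmark_series.values
                    + np.random.default_rng(2).normal(0, 0.02,
                                                      benchmark_series.values.shape),
                    1e-6, None)
        )
        report = parameter_confidence(spec.truth, noisy, constraints=cons)
        mags = np.concatenate([np.abs(spec.truth.alpha),
                               np.abs(spec.truth.beta.ravel())])
        scores = np.concatenate([report.alpha_score, report.beta_score.ravel()])
        keep = mags > 0
        rho = spearmanr(mags[keep], scores[keep]).statistic
        assert rho > 0


class TestEnsembleSummaries:
    def test_identical_members_mean_equals_single(self, benchmark, benchmark_series):
        spec, cons = benchmark
        ens = toy_ensemble([spec.truth, spec.truth])
        mean_report = ensemble_confidence(ens, benchmark_series, constraints=cons)
        single = parameter_confidence(spec.truth, benchmark_series,
                                      constraints=cons)
        assert np.allclose(mean_report.beta_score, single.beta_score)

    def test_mean_score_bounded_by_max_member(self, benchmark, benchmark_series):
        spec, cons = benchmark
        other = GLVParameters(alpha=spec.truth.alpha * 1.1,
                              beta=spec.truth.beta * 0.9)
        ens = toy_ensemble([spec.truth, other])
        mean_report = ensemble_confidence(ens, benchmark_series, constraints=cons)
        reports = [
            parameter_confidence(p, benchmark_series, constraints=cons)
            for p in (spec.truth, other)
        ]
        elementwise_max = np.maximum(reports[0].beta_score, reports[1].beta_score)
        assert np.all(mean_report.beta_score <= elementwise_max + 1e-12)

    def test_cv_identical_members_zero(self, benchmark):
        spec, _ = benchmark
        acv, bcv = parameter_cv(toy_ensemble([spec.truth, spec.truth]))
        assert np.allclose(acv, 0.0)
        nz = spec.truth.beta != 0
        assert np.allclose(bcv[nz], 0.0)

    def test_cv_two_member_arithmetic(self):
        p1 = GLVParameters(alpha=[1.0], beta=[[-1.0]])
        p2 = GLVParameters(alpha=[3.0], beta=[[-1.0]])
        acv, _ = parameter_cv(toy_ensemble([p1, p2]))
        assert acv[0] == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_cv_matches_naive_recomputation(self, rng):
        params = [
            GLVParameters(alpha=rng.uniform(0.5, 1.5, 2),
                          beta=-rng.uniform(0.5, 1.5, (2, 2)))
            for _ in range(5)
        ]
        acv, bcv = parameter_cv(toy_ensemble(params))
        alphas = np.stack([p.alpha for p in params])
        betas = np.stack([p.beta for p in params])
        assert np.allclose(acv, alphas.std(axis=0, ddof=1) / np.abs(alphas.mean(axis=0)))
        assert np.allclose(bcv, betas.std(axis=0, ddof=1) / np.abs(betas.mean(axis=0)))

    def test_cv_zero_mean_undefined(self):
        p1 = GLVParameters(alpha=[1.0], beta=[[-1.0]])
        p2 = GLVParameters(alpha=[-1.0], beta=[[-1.0]])
        acv, _ = parameter_cv(toy_ensemble([p1, p2]))
        assert np.isnan(acv[0])


class TestSusceptibility:
    # weakly coupled community: the one-at-a-time fitting protocol is only
    # consistent when cross-species feedback is small
    times = np.arange(0.0, 51.0, 2.5)
    truth = GLVParameters(
        alpha=np.array([0.8, 0.5, 0.6]),
        beta=np.array([[-1.0, -0.05, 0.0],
                       [-0.05, -0.9, -0.05],
                       [0.0, -0.05, -0.7]]),
        epsilon=np.array([0.5, 0.0, -0.3]),
    )
    x0 = np.array([0.4, 0.5, 0.3])

    def exogenous(self):
        return ExogenousSeries(
            times=self.times,
            values=0.5 + 0.4 * np.sin(self.times / 8.0),
        )

    def test_zero_exogenous_series_unidentifiable(self, benchmark, benchmark_series):
        spec, _ = benchmark
        exo = ExogenousSeries(times=benchmark_series.times,
                              values=np.zeros(benchmark_series.n_times))
        fit = fit_susceptibility(spec.truth, benchmark_series, exo)
        assert np.all(fit.epsilon == 0.0)
        assert np.all(fit.score == 0.0)

    def test_recovers_known_susceptibilities(self):
        """Data generated with eps = (0.5, 0, -0.3): nonzero entries recovered
        within 10%, the null entry stays near zero, across noise seeds."""
        exo = self.exogenous()
        clean = simulate_glv_exogenous(self.truth, self.x0, self.times, exo)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean.with_values(
                np.clip(clean.values + rng.normal(0, 0.005, clean.values.shape),
                        1e-6, None)
            )
            fit = fit_susceptibility(
                self.truth.with_epsilon(None), noisy, exo
            )
            ok = (abs(fit.epsilon[0] - 0.5) < 0.05
                  and abs(fit.epsilon[2] + 0.3) < 0.03
                  and abs(fit.epsilon[1]) < 0.05)
            hits += ok
        assert hits >= 18

    def test_frozen_coefficients_reproduce_trajectories(self, benchmark, benchmark_series):
        """With the exogenous term absent the member's trajectories are
        untouched by the susceptibility machinery."""
        spec, _ = benchmark
        again = simulate_glv(spec.truth, spec.x0, spec.times)
        assert np.array_equal(again.values, benchmark_series.values)
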