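"""Adaptive-trial loop and the multivariate-t stopping criterion."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import mbaod
from mbaod import scenario
from mbaod.config import default_config
from mbaod.design import ParameterPrior
from mbaod.trial import (
    StoppingDeferred,
    TooFewSubjectsError,
    degrees_of_freedom,
    evaluate_stopping,
    sample_fixed_effects,
    scale_matrix,
)


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "n_id,expected", [(8, 2.5), (10, 4.5), (20, 14.5)]
    )
    def test_scenario_counts(self, n_id, expected):
        assert degrees_of_freedom(n_id, 4, 3) == pytest.approx(expected)

    def test_too_few_subjects(self):
        with pytest.raises(TooFewSubjectsError):
            degrees_of_freedom(5, 4, 3)


class TestScaleMatrix:
    def test_identity_covariance(self):
        np.testing.assert_allclose(scale_matrix(np.eye(3), 4.0), 0.5 * np.eye(3))

    def test_limit_recovers_covariance(self):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(scale_matrix(cov, 1e9), cov, rtol=1e-8)

    def test_low_df_defers(self):
        with pytest.raises(StoppingDeferred):
            scale_matrix(np.eye(2), 2.0)

    def test_draw_covariance_identity(self):
        # Monte-Carlo identity: Cov(draws) = S*df/(df-2) = COV.
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        cov = A @ A.T + np.eye(4)
        df = 10.0
        S = scale_matrix(cov, df)
        draws = sample_fixed_effects(np.zeros(4), S, df, 1_000_000, seed=1)
        np.testing.assert_allclose(np.cov(draws.T), cov, rtol=0.02, atol=0.02)


class TestSampleFixedEffects:
    def test_zero_scale_returns_location(self):
        beta = np.array([1.0, 100.0, 7.0, 2.0])
        draws = sample_fixed_effects(beta, np.zeros((4, 4)), 5.0, 100, seed=0)
        assert np.all(draws == beta)

    def test_location_recovered(self):
        beta = np.array([1.0, 100.0, 7.0, 2.0])
        S = np.diag([0.01, 25.0, 0.5, 0.05])
        draws = sample_fixed_effects(beta, S, 10.0, 1_000_000, seed=2)
        se = np.sqrt(np.diag(S) * 10 / 8 / 1e6)
        assert np.all(np.abs(draws.mean(axis=0) - beta) < 3.5 * se)

    def test_marginal_kurtosis_matches_df(self):
        # Excess kurtosis of t(df) is 6/(df-4); df=10 gives 1.0.
        draws = sample_fixed_effects(np.zeros(1), np.eye(1), 10.0, 2_000_000, seed=3)
        x = draws[:, 0]
        kurt = np.mean((x - x.mean()) ** 4) / np.var(x) ** 2 - 3.0
        assert kurt == pytest.approx(1.0, abs=0.15)

    def test_reproducible(self):
        a = sample_fixed_effects(np.zeros(2), np.eye(2), 5.0, 100, seed=9)
        b = sample_fixed_effects(np.zeros(2), np.eye(2), 5.0, 100, seed=9)
        np.testing.assert_array_equal(a, b)


class TestEvaluateStopping:
    def test_degenerate_draws_stop(self, theta_true, sparse_design):
        beta = np.array([theta_true.value(n) for n in theta_true.estimated_beta])
        sim = np.tile(beta, (500, 1))
        rep = evaluate_stopping(sim, theta_true.estimated_beta, theta_true, sparse_design)
        assert rep.stop and rep.table["within"].all()

    def test_single_outlier_outside_ci_level_ignored(self, theta_true, sparse_design):
        beta = np.array([theta_true.value(n) for n in theta_true.estimated_beta])
        sim = np.tile(beta, (1000, 1))
        sim[0, 1] *= 10  # one wild EMAX draw, excluded by the 95% quantiles
        rep = evaluate_stopping(sim, theta_true.estimated_beta, theta_true, sparse_design)
        assert rep.stop

    def test_ci_touching_band_edge_is_within(self, theta_true):
        # Construct draws whose upper quantile lands exactly on 1.40*ref:
        # a two-point distribution around the reference at a placebo arm,
        # where the response is just the baseline.
        design = mbaod.StudyDesign((mbaod.GroupDesign(0, 1, (1.0,)),))
        base_ref = theta_true.fixed.base
        sim = np.column_stack(
            [
                np.concatenate(
                    [np.full(975, 1.40 * base_ref), np.full(25, 1.40 * base_ref)]
                ),
                np.full(1000, 100.0),
                np.full(1000, 7.0),
                np.full(1000, 2.0),
            ]
        )
        rep = evaluate_stopping(sim, theta_true.estimated_beta, theta_true, design)
        row = rep.table.iloc[0]
        assert row["ci_upper"] == pytest.approx(1.40 * base_ref)
        assert bool(row["within"])

    def test_wide_band_is_monotone(self, theta_true, sparse_design):
        rng = np.random.default_rng(5)
        beta = np.array([theta_true.value(n) for n in theta_true.estimated_beta])
        sim = beta * np.exp(rng.normal(0, 0.2, size=(2000, 4)))
        narrow = evaluate_stopping(
            sim, theta_true.estimated_beta, theta_true, sparse_design, band=(0.9, 1.1)
        )
        wide = evaluate_stopping(
            sim, theta_true.estimated_beta, theta_true, sparse_design, band=(0.2, 5.0)
        )
        if narrow.stop:
            assert wide.stop


class TestUpdates:
    def _fit_like(self, theta, cov=None, converged=True, repaired=False):
        return mbaod.EstimationResult(
            theta_hat=theta,
            ofv=0.0,
            cov_beta=cov,
            beta_names=theta.estimated_beta,
            converged=converged,
            n_id=8,
            method="FOCEI",
            cov_repaired=repaired,
        )

    def test_update_guess_replaces_estimated_only(self, theta_true, theta_guess):
        fit = self._fit_like(theta_true)
        updated = mbaod.update_guess(theta_guess, fit)
        for name in theta_guess.estimated:
            assert updated.value(name) == theta_true.value(name)
        for name in ("cl", "v", "ka", "omega2_cl", "omega2_v", "sigma2_add"):
            assert updated.value(name) == theta_guess.value(name)

    def test_update_guess_identity_and_unconverged(self, theta_guess):
        fit = self._fit_like(theta_guess)
        assert mbaod.update_guess(theta_guess, fit) == theta_guess
        bad = self._fit_like(theta_guess, converged=False)
        assert mbaod.update_guess(theta_guess, bad) == theta_guess

    def test_update_prior_from_covariance(self, theta_true):
        cov = np.diag([4.0, 9.0, 1.0, 0.25])
        fit = self._fit_like(theta_true, cov=cov)
        prior = ParameterPrior(
            mean={n: 1.0 for n in theta_true.estimated_beta},
            sd={n: 0.1 for n in theta_true.estimated_beta},
        )
        new = mbaod.update_prior(prior, fit)
        assert new.sd["base"] == 2.0 and new.sd["emax"] == 3.0
        assert new.mean["emax"] == theta_true.fixed.emax

    def test_update_prior_zero_covariance_collapses_to_point(self, theta_true):
        fit = self._fit_like(theta_true, cov=np.zeros((4, 4)))
        prior = ParameterPrior(
            mean={n: 1.0 for n in theta_true.estimated_beta},
            sd={n: 0.1 for n in theta_true.estimated_beta},
        )
        new = mbaod.update_prior(prior, fit)
        assert all(s == 0.0 for s in new.sd.values())

    def test_update_prior_keeps_sd_when_repaired(self, theta_true):
        # A clipped-eigenvalue (nearest-PD) covariance signals an
        # unidentified ridge; its diagonal would make the prior noise, so
        # only the mean moves.
        fit = self._fit_like(theta_true, cov=4.0 * np.eye(4), repaired=True)
        prior = ParameterPrior(
            mean={n: 1.0 for n in theta_true.estimated_beta},
            sd={n: 0.1 for n in theta_true.estimated_beta},
        )
        new = mbaod.update_prior(prior, fit)
        assert all(s == 0.1 for s in new.sd.values())
        assert new.mean["emax"] == theta_true.fixed.emax

    def test_update_prior_keeps_sd_when_covariance_absent(self, theta_true):
        fit = self._fit_like(theta_true, cov=None)
        prior = ParameterPrior(
            mean={n: 1.0 for n in theta_true.estimated_beta},
            sd={n: 0.1 for n in theta_true.estimated_beta},
        )
        new = mbaod.update_prior(prior, fit)
        assert all(s == 0.1 for s in new.sd.values())


class TestRunMbaod:
    def test_vacuous_band_stops_after_first_cohort(self):
        cfg = default_config(
            max_cohorts=5, n_stop_sim=500, seed=123, band=(1e-9, 1e9)
        )
        h = mbaod.run_mbaod(cfg, replicate=0)
        assert h.status == "stopped"
        assert h.n_cohorts == 1 and h.total_n_id == 8

    def test_single_cohort_budget(self):
        cfg = default_config(max_cohorts=1, n_stop_sim=500, seed=123)
        h = mbaod.run_mbaod(cfg, replicate=0)
        assert h.n_cohorts == 1
        assert h.status in ("stopped", "max-cohorts-reached")

    def test_identical_seeds_identical_histories(self):
        cfg = default_config(max_cohorts=3, n_stop_sim=500, seed=42)
        a = mbaod.run_mbaod(cfg, replicate=1)
        b = mbaod.run_mbaod(cfg, replicate=1)
        assert a.status == b.status and a.chosen_doses() == b.chosen_doses()
        for ca, cb in zip(a.cohorts, b.cohorts):
            assert ca.fit.ofv == cb.fit.ofv
            assert ca.fim_true_logdet == cb.fim_true_logdet
            pd.testing.assert_frame_equal(ca.stopping.table, cb.stopping.table)

    def test_point_prior_eld_replays_lnd_dose_sequence(self, theta_true):
        # With the true parameters as the initial guess, a zero-sd frozen
        # prior and shared seeds, the robust criterion degenerates to the
        # local one and both arms must choose identical dose sequences.
        base = default_config(
            max_cohorts=3, n_stop_sim=500, seed=77, criterion="lnD",
            theta_init=theta_true, prior_cv=0.0, update_priors=False,
            band=(0.999, 1.001),  # effectively never stop within 3 cohorts
        )
        lnd = mbaod.run_mbaod(base, replicate=0)
        eld = mbaod.run_mbaod(dataclasses.replace(base, criterion="ELD"), replicate=0)
        assert lnd.chosen_doses() == eld.chosen_doses()
        assert len(lnd.chosen_doses()) == 2

    def test_bookkeeping_and_monotone_information(self, mini_histories):
        for h in mini_histories:
            for k, rec in enumerate(h.cohorts, start=1):
                assert rec.cumulative_design.n_total == 8 + 2 * (k - 1)
            logdets = [rec.fim_true_logdet for rec in h.cohorts]
            assert all(b >= a - 1e-9 for a, b in zip(logdets, logdets[1:]))
            assert h.total_n_id == 8 + 2 * (h.n_cohorts - 1)

    def test_history_persistence_round_trip(self, mini_histories, tmp_path):
        h = mini_histories[0]
        mbaod.save_history(h, tmp_path / "rep")
        back = mbaod.load_history(tmp_path / "rep")
        assert back.status == h.status
        assert back.chosen_doses() == h.chosen_doses()
        assert back.total_n_id == h.total_n_id
        assert back.data is not None and len(back.data) == len(h.data)
        np.testing.assert_allclose(
            [c.fim_true_logdet for c in back.cohorts],
            [c.fim_true_logdet for c in h.cohorts],
        )
        for ca, cb in zip(h.cohorts, back.cohorts):
            for name in ca.fit.theta_hat.estimated:
                assert cb.fit.theta_hat.value(name) == pytest.approx(
                    ca.fit.theta_hat.value(name)
                )
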