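import numpy as np
import pandas as pd
import pytest

import gravicept as gc
from gravicept.predictors import engagement_column


@pytest.fixture(scope="module")
def tiny_sampler():
    return gc.SamplerConfig(n_walkers=32, n_steps=400, n_burn=150, seed=3,
                            n_draws=2000, compute_loo=False)


def _simulate_summaries(predictor_table, **overrides):
    params = gc.GenerativeParams(**overrides)
    trials = gc.filter_outliers(gc.simulate_trials(params, predictor_table))
    return gc.aggregate(trials)


class TestFitMixed:
    def test_noise_free_recovery(self, predictor_table, tiny_sampler):
        """Data lying exactly on the unit-slope line pin the posterior."""
        summ = _simulate_summaries(
            predictor_table, beta0=0.0, beta_grav=1.0, sd_intercept=0.0,
            sd_slope=0.0, cor_int_slope=0.0, sigma_cond=0.0, sigma_trial=0.0,
            seed=1,
        )
        fit = gc.fit_mixed(summ, predictor_table, ("g_450",), settings=tiny_sampler)
        slope = fit.summary.loc["b_g_450", "mean"]
        assert slope == pytest.approx(1.0, abs=0.01)
        lo, hi = fit.summary.loc["b_Intercept", ["hdi_3%", "hdi_97%"]]
        assert lo <= 0.0 <= hi

    def test_parameter_recovery_at_generative_truth(self, default_fit, predictor_table):
        """The slope posterior brackets the generative 0.99 and the
        random-intercept SD posterior brackets the realized spread of the
        simulated subjects' intercepts."""
        s = default_fit.summary
        slope, slope_sd = s.loc["b_g_450", ["mean", "sd"]]
        assert abs(slope - 0.99) < 3.0 * slope_sd
        # noise-free twin of the same seed exposes the exact per-subject
        # random effects (the noise draws are zeroed, the stream is shared)
        twin = gc.simulate_trials(
            gc.GenerativeParams(seed=11, sigma_cond=0.0, sigma_trial=0.0),
            predictor_table,
        )
        lines = twin.groupby("subject_id").apply(
            lambda d: np.polyfit(
                d["duration_s"] * 0.0
                + predictor_table.loc[
                    list(zip(d["label"], d["duration_s"])), "g_450"
                ].to_numpy(),
                d["rt_ms"],
                1,
            )[1],
            include_groups=False,
        )
        realized_sd = float(lines.std(ddof=1))
        sd_lo, sd_hi = s.loc["sd_Intercept", ["hdi_3%", "hdi_97%"]]
        assert sd_lo < realized_sd < sd_hi
        assert default_fit.draws == 4000

    def test_linear_equivariance_under_scaling(self, predictor_table, tiny_sampler):
        """Doubling all response times doubles intercept, sigma and the
        slope-predictor relationship."""
        summ = _simulate_summaries(predictor_table, seed=6, n_subjects=16)
        doubled = summ.assign(mean_rt=2.0 * summ["mean_rt"])
        f1 = gc.fit_mixed(summ, predictor_table, ("g_450",), settings=tiny_sampler)
        f2 = gc.fit_mixed(doubled, predictor_table, ("g_450",), settings=tiny_sampler)
        s1, s2 = f1.summary, f2.summary
        assert s2.loc["sigma", "mean"] == pytest.approx(2 * s1.loc["sigma", "mean"], rel=0.15)
        assert s2.loc["b_g_450", "mean"] == pytest.approx(2 * s1.loc["b_g_450", "mean"], rel=0.05)

    def test_unbalanced_rows_rejected(self, default_summaries, predictor_table):
        with pytest.raises(ValueError):
            gc.fit_mixed(default_summaries.iloc[:-5], predictor_table)

    def test_unknown_predictor_column_rejected(self, default_summaries, predictor_table):
        with pytest.raises(ValueError):
            gc.fit_mixed(default_summaries, predictor_table, ("nope",))

    def test_point_estimates_agree_with_classical_mixed_model(
        self, default_summaries, predictor_table, default_fit
    ):
        """Independent oracle: a likelihood-based mixed model (statsmodels
        MixedLM) lands where the posterior concentrates."""
        sm = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        df = default_summaries.merge(
            predictor_table[[engagement_column(450)]].reset_index(),
            left_on=["label", "duration_s"],
            right_on=["label", "duration"],
        )
        model = sm.MixedLM.from_formula(
            "mean_rt ~ g_450", groups="subject_id", re_formula="~g_450", data=df
        )
        res = model.fit(reml=True)
        assert default_fit.summary.loc["b_g_450", "mean"] == pytest.approx(
            res.params["g_450"], abs=0.02
        )
        assert default_fit.summary.loc["sigma", "mean"] ** 2 == pytest.approx(
            res.scale, rel=0.25
        )


class TestBayesR2:
    def test_zero_noise_r2_near_one(self, predictor_table, tiny_sampler):
        summ = _simulate_summaries(
            predictor_table, sd_intercept=0.0, sd_slope=0.0, cor_int_slope=0.0,
            sigma_cond=0.0, sigma_trial=0.0, seed=2,
        )
        fit = gc.fit_mixed(summ, predictor_table, ("g_450",), settings=tiny_sampler)
        assert gc.bayes_r2(fit)["mean"] > 0.99

    def test_pure_noise_r2_near_zero(self, predictor_table, tiny_sampler):
        rng = np.random.default_rng(0)
        rows = [
            dict(subject_id=s, label=lab, duration_s=dur, mean_rt=rng.normal(0, 30))
            for s in range(16)
            for (lab, dur) in predictor_table.index
        ]
        fit = gc.fit_mixed(pd.DataFrame(rows), predictor_table, ("g_450",),
                           settings=tiny_sampler)
        assert gc.bayes_r2(fit)["mean"] < 0.3

    def test_augmented_r2_not_below_nested(self, default_summaries, predictor_table,
                                           default_fit, tiny_sampler):
        aug = gc.fit_mixed(default_summaries, predictor_table, ("g_450", "optical"),
                           settings=tiny_sampler)
        assert aug.bayes_r2_mean >= default_fit.bayes_r2_mean - 0.01


class TestPosteriorChecks:
    def test_posterior_predictive_envelope(self, default_fit):
        """Observed data statistics sit inside the replicated-data spread."""
        reps = default_fit.posterior_predictive(seed=0, n_draws=500)
        obs_mean, obs_sd = default_fit.y.mean(), default_fit.y.std(ddof=1)
        rep_means, rep_sds = reps.mean(axis=1), reps.std(axis=1, ddof=1)
        assert rep_means.min() < obs_mean < rep_means.max()
        assert rep_sds.min() < obs_sd < rep_sds.max()
        for q in (0.1, 0.5, 0.9):
            rep_q = np.quantile(reps, q, axis=1)
            assert rep_q.min() < np.quantile(default_fit.y, q) < rep_q.max()

    def test_observed_vs_predicted_near_unit_slope(self, default_fit):
        slope = np.polyfit(default_fit.mu_mean, default_fit.y, 1)[0]
        assert 0.9 < slope < 1.1


class TestScan:
    def test_profile_unimodal_around_generative_time(self, default_summaries,
                                                     predictor_table):
        cfg = gc.SamplerConfig(n_walkers=64, n_steps=700, n_burn=300, seed=0,
                               compute_loo=False)
        res = gc.scan_engagement_times(
            default_summaries, predictor_table,
            grid_ms=range(300, 601, 50), settings=cfg,
        )
        prof = res.profile.set_index("engagement_ms")
        assert res.best_time == 450
        r2 = prof["bayes_r2"]
        peak = r2.idxmax()
        assert r2.loc[:peak].is_monotonic_increasing
        assert r2.loc[peak:].is_monotonic_decreasing
        # lowest expected error variance coincides with highest R2
        assert prof["sigma2"].idxmin() == peak

    def test_onset_engagement_recovered(self, predictor_table):
        """Data generated from the onset predictor select engagement 0."""
        summ = _simulate_summaries(predictor_table, engagement_ms=0, seed=8)
        cfg = gc.SamplerConfig(n_walkers=64, n_steps=700, n_burn=300, seed=1,
                               compute_loo=False)
        res = gc.scan_engagement_times(summ, predictor_table,
                                       grid_ms=[0, 50, 100], settings=cfg)
        assert res.best_time == 0


class TestLooComparison:
    def test_self_comparison_is_null(self, predictor_table):
        cfg = gc.SamplerConfig(n_walkers=64, n_steps=700, n_burn=300, seed=4)
        summ = _simulate_summaries(predictor_table, seed=3, n_subjects=12)
        fit = gc.fit_mixed(summ, predictor_table, ("g_450",), settings=cfg)
        res = gc.compare_loo(fit, fit)
        assert res["elpd_diff"] == pytest.approx(0.0, abs=1e-9)
        assert not res["significant"]

    def test_requires_loo_and_identical_data(self, predictor_table, tiny_sampler):
        summ = _simulate_summaries(predictor_table, seed=3, n_subjects=8)
        no_loo = gc.fit_mixed(summ, predictor_table, ("g_450",), settings=tiny_sampler)
        with pytest.raises(ValueError):
            gc.compare_loo(no_loo, no_loo)
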