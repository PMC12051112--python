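"""Individual-series forecasting: oracle equivalence and GP sanity properties."""

import numpy as np
import pytest

import methylgp as mgp
from methylgp.forecasting import (
    batch_forecast,
    cpg_mean_posterior,
    forecast_frame,
    predict_individual,
)
from methylgp.gp_core import KernelParams, se_kernel
from methylgp.model import MethylationSeriesSet, ModelHyperparams, MultiMeanGP, e_step

from conftest import condition_explicit, joint_model_gaussian, random_hyperparams


def _manual_model(hp, grid, data):
    """Assemble a fitted-model object directly from an E-step (no EM)."""
    model = MultiMeanGP()
    model.hyperparams_ = hp
    model.pooled_grid_ = np.asarray(grid, float)
    model.mean_posteriors_ = e_step(data, hp, grid)
    model.prior_mean_by_cpg_ = {c: hp.prior_mean_constant for c in data.cpgs}
    return model


class TestCpgMeanPosterior:
    def test_identity_on_training_grid(self, small_model):
        cpg = small_model.cpgs_[0]
        stored = small_model.mean_posteriors_[cpg]
        out = cpg_mean_posterior(small_model, cpg, small_model.pooled_grid_)
        np.testing.assert_allclose(out.mean, stored.mean, atol=1e-6)
        np.testing.assert_allclose(out.cov, stored.cov, atol=1e-6)

    def test_reverts_to_prior_far_from_data(self, small_model):
        cpg = small_model.cpgs_[0]
        hp = small_model.hyperparams_
        far = np.array([56.0])
        out = cpg_mean_posterior(small_model, cpg, far)
        prior_var = (
            se_kernel(far, far, hp.theta0) + se_kernel(far, far, hp.theta_g_for(cpg))
        )[0, 0]
        assert out.cov[0, 0] == pytest.approx(prior_var, rel=0.01)
        assert out.mean[0] == pytest.approx(small_model.prior_mean_by_cpg_[cpg], abs=1e-3)

    def test_unknown_cpg_raises(self, small_model):
        with pytest.raises(KeyError, match="unknown CpG"):
            cpg_mean_posterior(small_model, "cg9999999", [1.0])


class TestPredictIndividual:
    def test_no_observations_gives_prior_predictive(self, small_model):
        cpg = small_model.cpgs_[0]
        targets = [2.0, 6.0]
        fr = predict_individual(small_model, cpg, [], targets)
        mp = cpg_mean_posterior(small_model, cpg, targets)
        np.testing.assert_allclose(fr.belief.mean, mp.mean, atol=1e-9)
        hp = small_model.hyperparams_
        extra = np.diag(se_kernel(targets, targets, hp.theta_f)) + hp.sigma2_for(cpg)
        np.testing.assert_allclose(
            np.diag(fr.belief.cov), np.diag(mp.cov) + extra, rtol=1e-6
        )

    def test_noiseless_interpolation_reproduces_observation(self):
        # tiny noise, tiny mean-process uncertainty: forecast pins the datum
        grid = np.array([0.25, 0.75, 4.05])
        hp = ModelHyperparams(
            theta0=KernelParams(-3.0, 1.0),
            theta_g=KernelParams(-4.0, 1.0),
            theta_f=KernelParams(-4.5, 0.5),
            noise_variance=1e-10,
            prior_mean_constant=0.5,
        )
        recs = [(f"i{k}", "cg1", t, 0.5 + 0.02 * k) for k in range(8) for t in grid]
        data = MethylationSeriesSet.from_records(recs)
        model = _manual_model(hp, grid, data)
        fr = predict_individual(model, "cg1", [(0.75, 0.71)], [0.75])
        assert fr.belief.mean[0] == pytest.approx(0.71, abs=1e-4)

    def test_matches_exhaustive_joint_gaussian_oracle(self):
        rng = np.random.default_rng(17)
        obs_times = [0.25, 0.75, 4.05]
        target = 6.05
        grid = np.array(obs_times + [target])
        for _ in range(4):
            hp = random_hyperparams(rng)
            train_blocks = [
                ("i1", list(grid), rng.uniform(0.3, 0.7, 4)),
                ("i2", list(grid), rng.uniform(0.3, 0.7, 4)),
            ]
            recs = [
                (ind, "cg1", t, y) for ind, ts, ys in train_blocks for t, y in zip(ts, ys)
            ]
            data = MethylationSeriesSet.from_records(recs)
            model = _manual_model(hp, grid, data)
            y_test = rng.uniform(0.3, 0.7, 3)
            fr = predict_individual(
                model, "cg1", list(zip(obs_times, y_test)), [target]
            )

            # oracle: condition the full joint over (m, y_train, y_test) directly
            blocks = train_blocks + [("i_test", list(grid), np.zeros(4))]
            mean, cov, slices = joint_model_gaussian(grid, blocks, hp)
            s_test = slices[-1]
            obs_idx = np.concatenate(
                [np.arange(s.start, s.stop) for s in slices[:-1]]
                + [np.arange(s_test.start, s_test.start + 3)]
            )
            obs_val = np.concatenate([ys for _, _, ys in train_blocks] + [y_test])
            ref_mean, ref_cov = condition_explicit(mean, cov, obs_idx, obs_val)
            # retained: m on grid (4) then y_test at the target
            assert fr.belief.mean[0] == pytest.approx(ref_mean[-1], rel=1e-6, abs=1e-8)
            assert fr.belief.cov[0, 0] == pytest.approx(ref_cov[-1, -1], rel=1e-4, abs=1e-9)

    def test_extrapolation_variance_grows_beyond_last_observation(self, small_model):
        cpg = small_model.cpgs_[0]
        fr = predict_individual(
            small_model, cpg, [(0.25, 0.5), (0.75, 0.55), (4.05, 0.6)],
            [4.5, 5.0, 6.0, 8.0, 12.0],
        )
        var = np.diag(fr.belief.cov)
        assert np.all(np.diff(var) > 0)

    def test_distinct_histories_give_distinct_forecasts(self, small_model):
        cpg = small_model.cpgs_[0]
        a = predict_individual(small_model, cpg, [(0.25, 0.3), (4.05, 0.35)], [6.05])
        b = predict_individual(small_model, cpg, [(0.25, 0.7), (4.05, 0.75)], [6.05])
        assert abs(a.belief.mean[0] - b.belief.mean[0]) > 1e-3

    def test_invalid_inputs_raise(self, small_model):
        cpg = small_model.cpgs_[0]
        with pytest.raises(KeyError):
            predict_individual(small_model, "cgNOPE", [], [6.0])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            predict_individual(small_model, cpg, [(0.25, 1.4)], [6.0])
        with pytest.raises(ValueError, match="non-empty"):
            predict_individual(small_model, cpg, [], [])


class TestBatchForecast:
    def test_unit_case_and_agreement_with_single_path(self, small_cohort, small_model):
        obs = small_cohort["test_observed"]
        ind = obs.individuals[0]
        cpg = small_model.cpgs_[0]
        single = obs.filter(individuals=[ind], cpgs=[cpg])
        results = batch_forecast(small_model, single, [6.05], [cpg])
        assert len(results) == 1
        t, y = obs.series(ind, cpg)
        direct = predict_individual(
            small_model, cpg, list(zip(t, y)), [6.05], individual_id=ind
        )
        np.testing.assert_allclose(
            results[0].belief.mean, direct.belief.mean, rtol=1e-8
        )
        np.testing.assert_allclose(results[0].belief.cov, direct.belief.cov, rtol=1e-6)

    def test_count_and_order_invariance(self, small_cohort, small_model):
        obs = small_cohort["test_observed"]
        panel = small_model.cpgs_
        results = batch_forecast(small_model, obs, [6.05], panel)
        assert len(results) == len(obs.individuals) * len(panel)
        # permute individuals by reversing the input frame
        shuffled = mgp.MethylationSeriesSet(
            obs.frame.iloc[::-1].reset_index(drop=True)
        )
        again = batch_forecast(small_model, shuffled, [6.05], panel)
        for r1, r2 in zip(results, again):
            assert (r1.individual_id, r1.cpg_id) == (r2.individual_id, r2.cpg_id)
            np.testing.assert_allclose(r1.belief.mean, r2.belief.mean, atol=1e-12)

    def test_individual_without_observations_gets_prior_predictive(
        self, small_cohort, small_model
    ):
        obs = small_cohort["test_observed"]
        cpgs = small_model.cpgs_
        # drop one individual's records for the first CpG entirely
        ind = obs.individuals[0]
        frame = obs.frame
        mask = (frame["individual_id"] == ind) & (frame["cpg_id"] == cpgs[0])
        pruned = mgp.MethylationSeriesSet(frame[~mask].reset_index(drop=True))
        results = batch_forecast(small_model, pruned, [6.05], cpgs)
        assert len(results) == len(obs.individuals) * len(cpgs)
        got = next(r for r in results if (r.individual_id, r.cpg_id) == (ind, cpgs[0]))
        prior = predict_individual(small_model, cpgs[0], [], [6.05], individual_id=ind)
        np.testing.assert_allclose(got.belief.mean, prior.belief.mean, atol=1e-9)

    def test_empty_panel_rejected(self, small_cohort, small_model):
        with pytest.raises(ValueError, match="panel"):
            batch_forecast(small_model, small_cohort["test_observed"], [6.05], [])


class TestForecastFrame:
    def test_table_layout_and_interval(self, small_cohort, small_model):
        results = batch_forecast(
            small_model, small_cohort["test_observed"], [5.0, 6.05], small_model.cpgs_
        )
        frame = forecast_frame(results)
        assert list(frame.columns) == [
            "individual_id",
            "cpg_id",
            "target_time",
            "pred_mean",
            "pred_sd",
            "ci95_lower",
            "ci95_upper",
        ]
        assert len(frame) == len(results) * 2
        np.testing.assert_allclose(
            frame["ci95_upper"] - frame["pred_mean"], 1.96 * frame["pred_sd"]
        )
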