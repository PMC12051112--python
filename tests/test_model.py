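"""Additive-model E-step/M-step machinery and the EM fit."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import methylgp as mgp
from methylgp.gp_core import KernelParams, se_kernel
from methylgp.model import (
    MethylationSeriesSet,
    ModelHyperparams,
    MultiMeanGP,
    _FitIndex,
    e_step,
    em_objective,
    m_step,
    pooled_timestamps,
)

from conftest import condition_explicit, joint_model_gaussian, random_hyperparams


class TestMethylationSeriesSet:
    def test_rejects_beta_outside_unit_interval(self):
        with pytest.raises(ValueError, match="beta"):
            MethylationSeriesSet.from_records([("a", "cg1", 0.5, 1.2)])

    def test_rejects_duplicate_triples(self):
        recs = [("a", "cg1", 0.5, 0.4), ("a", "cg1", 0.5, 0.6)]
        with pytest.raises(ValueError, match="duplicate"):
            MethylationSeriesSet.from_records(recs)

    def test_rejects_negative_age_and_empty_input(self):
        with pytest.raises(ValueError, match="age"):
            MethylationSeriesSet.from_records([("a", "cg1", -0.5, 0.4)])
        with pytest.raises(ValueError, match="empty"):
            MethylationSeriesSet.from_records([])

    def test_series_lookup_is_time_sorted(self):
        recs = [("a", "cg1", 4.0, 0.6), ("a", "cg1", 0.2, 0.4), ("b", "cg1", 1.0, 0.5)]
        data = MethylationSeriesSet.from_records(recs)
        t, y = data.series("a", "cg1")
        np.testing.assert_array_equal(t, [0.2, 4.0])
        np.testing.assert_array_equal(y, [0.4, 0.6])


class TestPooledTimestamps:
    def test_union_with_extra_times(self):
        data = MethylationSeriesSet.from_records(
            [("a", "cg1", 0.25, 0.5), ("b", "cg1", 0.75, 0.5)]
        )
        np.testing.assert_array_equal(
            pooled_timestamps(data, [6.0]), [0.25, 0.75, 6.0]
        )

    def test_duplicates_collapse(self):
        data = MethylationSeriesSet.from_records(
            [("a", "cg1", 0.25, 0.5), ("b", "cg1", 0.25, 0.6), ("b", "cg1", 1.0, 0.6)]
        )
        grid = pooled_timestamps(data, None)
        np.testing.assert_array_equal(grid, [0.25, 1.0])
        assert np.all(np.diff(grid) > 0)


class TestEStep:
    def test_no_observations_returns_the_prior(self):
        data = MethylationSeriesSet.from_records([("a", "cgA", 0.5, 0.4)])
        grid = np.array([0.5, 2.0])
        hp = random_hyperparams(np.random.default_rng(0))
        index = _FitIndex(data, grid)
        index.cpgs.append("cgEmpty")
        index.blocks["cgEmpty"] = []
        from methylgp.model import _e_step

        posts = _e_step(index, hp)
        prior = se_kernel(grid, grid, hp.theta0) + se_kernel(grid, grid, hp.theta_g)
        np.testing.assert_allclose(
            posts["cgEmpty"].mean, np.full(2, hp.prior_mean_constant)
        )
        np.testing.assert_allclose(posts["cgEmpty"].cov, prior, atol=1e-7)

    def test_noiseless_single_observation_is_interpolated(self):
        data = MethylationSeriesSet.from_records([("a", "cg1", 1.0, 0.8)])
        hp = ModelHyperparams(
            theta0=KernelParams(-3.0, 0.5),
            theta_g=KernelParams(-4.0, 0.5),
            theta_f=KernelParams(-30.0, 0.0),  # individual process ~ off
            noise_variance=1e-12,
            prior_mean_constant=0.5,
        )
        posts = e_step(data, hp, [1.0])
        assert posts["cg1"].mean[0] == pytest.approx(0.8, abs=1e-3)

    def test_matches_exhaustive_joint_gaussian_oracle(self):
        rng = np.random.default_rng(9)
        grid = np.array([0.25, 0.75, 4.0])
        for trial in range(5):
            hp = random_hyperparams(rng)
            blocks = [
                ("i1", [0.25, 0.75], rng.uniform(0.3, 0.7, 2)),
                ("i2", [0.75, 4.0], rng.uniform(0.3, 0.7, 2)),
                ("i3", [0.25, 4.0], rng.uniform(0.3, 0.7, 2)),
            ]
            recs = [
                (ind, "cg1", t, y)
                for ind, ts, ys in blocks
                for t, y in zip(ts, ys)
            ]
            data = MethylationSeriesSet.from_records(recs)
            posts = e_step(data, hp, grid)

            mean, cov, slices = joint_model_gaussian(grid, blocks, hp)
            obs_idx = np.concatenate([np.arange(s.start, s.stop) for s in slices])
            obs_val = np.concatenate([ys for _, _, ys in blocks])
            ref_mean, ref_cov = condition_explicit(mean, cov, obs_idx, obs_val)
            np.testing.assert_allclose(posts["cg1"].mean, ref_mean, rtol=1e-6, atol=1e-8)
            np.testing.assert_allclose(posts["cg1"].cov, ref_cov, rtol=1e-5, atol=1e-8)

    def test_posterior_variance_below_prior_and_shrinks_with_data(self):
        rng = np.random.default_rng(21)
        grid = np.array([0.25, 0.75, 4.0, 6.0])
        hp = random_hyperparams(rng)
        prior_var = np.diag(
            se_kernel(grid, grid, hp.theta0) + se_kernel(grid, grid, hp.theta_g)
        )
        recs1 = [("i1", "cg1", t, 0.5) for t in [0.25, 0.75]]
        recs2 = recs1 + [("i2", "cg1", t, 0.6) for t in [0.75, 4.0]]
        v1 = np.diag(e_step(MethylationSeriesSet.from_records(recs1), hp, grid)["cg1"].cov)
        v2 = np.diag(e_step(MethylationSeriesSet.from_records(recs2), hp, grid)["cg1"].cov)
        assert np.all(v1 <= prior_var + 1e-8)
        assert np.all(v2 <= v1 + 1e-8)


class TestEMObjective:
    def test_degenerate_posterior_reduces_to_plain_loglik(self):
        rng = np.random.default_rng(4)
        grid = np.array([0.25, 0.75, 4.0])
        hp = random_hyperparams(rng)
        recs = [("i1", "cg1", t, v) for t, v in zip(grid, [0.4, 0.5, 0.6])]
        data = MethylationSeriesSet.from_records(recs)
        fixed_mean = rng.uniform(0.3, 0.7, 3)
        posts = {"cg1": mgp.GaussianBelief(grid, fixed_mean, np.zeros((3, 3)))}
        got = em_objective(data, hp, posts)

        Kp = se_kernel(grid, grid, hp.theta0) + se_kernel(grid, grid, hp.theta_g)
        Psi = se_kernel(grid, grid, hp.theta_f) + hp.noise_variance * np.eye(3)
        expected = multivariate_normal(
            mean=fixed_mean, cov=Psi, allow_singular=True
        ).logpdf([0.4, 0.5, 0.6]) + multivariate_normal(
            mean=np.full(3, hp.prior_mean_constant), cov=Kp, allow_singular=True
        ).logpdf(fixed_mean)
        assert got == pytest.approx(expected, abs=1e-3)

    def test_dimension_mismatch_raises(self):
        data = MethylationSeriesSet.from_records([("a", "cg1", 0.5, 0.4)])
        # posterior grid does not cover the observed time
        bad = {"cg1": mgp.GaussianBelief([1.0, 2.0], [0.4, 0.4], np.eye(2) * 1e-4)}
        with pytest.raises(ValueError):
            em_objective(data, random_hyperparams(np.random.default_rng(1)), bad)


class TestMStep:
    def test_ascent_contract(self, small_cohort):
        data = small_cohort["train"]
        hp0 = random_hyperparams(np.random.default_rng(2))
        grid = pooled_timestamps(data, None)
        posts = e_step(data, hp0, grid)
        hp1 = m_step(data, posts, hp0, maxiter=15)
        assert em_objective(data, hp1, posts) >= em_objective(data, hp0, posts) - 1e-9


class TestFit:
    def test_refit_is_deterministic(self, small_cohort):
        a = MultiMeanGP(max_iter=3).fit(small_cohort["train"])
        b = MultiMeanGP(max_iter=3).fit(small_cohort["train"])
        assert a.training_summary_ == b.training_summary_
        np.testing.assert_array_equal(a.objective_trace_, b.objective_trace_)

    def test_objective_trace_is_monotone(self, small_model):
        assert np.all(np.diff(small_model.objective_trace_) >= -1e-6)

    def test_every_cpg_receives_a_posterior(self, small_cohort, small_model):
        assert set(small_model.mean_posteriors_) == set(small_cohort["train"].cpgs)
        grid = small_model.pooled_grid_
        for belief in small_model.mean_posteriors_.values():
            assert belief.order == grid.size
            assert np.all(np.isfinite(belief.mean))

    def test_rejects_degenerate_inputs(self):
        one_ind = MethylationSeriesSet.from_records(
            [("a", "cg1", 0.5, 0.4), ("a", "cg1", 1.0, 0.5)]
        )
        with pytest.raises(ValueError, match="individuals"):
            MultiMeanGP().fit(one_ind)
        one_time = MethylationSeriesSet.from_records(
            [("a", "cg1", 0.5, 0.4), ("b", "cg1", 0.5, 0.5)]
        )
        with pytest.raises(ValueError, match="timepoints"):
            MultiMeanGP().fit(one_time)
        with pytest.raises(ValueError, match="sharing"):
            MultiMeanGP(sharing="bogus").fit(one_ind)

    def test_sklearn_param_interface(self):
        est = MultiMeanGP(tol=1e-2)
        assert est.get_params()["tol"] == 1e-2
        est.set_params(max_iter=5)
        assert est.max_iter == 5

    def test_per_entity_sharing_smoke(self):
        cfg = mgp.SimulationConfig(n_train=4, n_test=1, n_cpgs=2, seed=5)
        train, *_ = mgp.simulate_cohort(cfg)
        model = MultiMeanGP(
            sharing="specific", noise_mode="per_cpg", max_iter=2, m_step_maxiter=8
        ).fit(train)
        assert isinstance(model.hyperparams_.theta_f, dict)
        assert isinstance(model.hyperparams_.noise_variance, dict)
        assert np.all(np.diff(model.objective_trace_) >= -1e-6)

    def test_serialization_roundtrip(self, small_model):
        payload = small_model.to_payload()
        clone = MultiMeanGP.from_payload(payload)
        cpg = small_model.cpgs_[0]
        np.testing.assert_allclose(
            clone.mean_posteriors_[cpg].mean, small_model.mean_posteriors_[cpg].mean
        )
        np.testing.assert_array_equal(clone.pooled_grid_, small_model.pooled_grid_)
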