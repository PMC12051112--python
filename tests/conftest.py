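"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use explicit matrix inverses and exhaustive
joint-Gaussian constructions (never the package's factorized code paths),
so they stay independent of the implementations they check.
"""

import numpy as np
import pytest

import methylgp as mgp
from methylgp.gp_core import se_kernel
from methylgp.model import ModelHyperparams


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny simulated cohort shared across tests (6 train, 4 test, 3 CpGs)."""
    cfg = mgp.SimulationConfig(n_train=6, n_test=4, n_cpgs=3, seed=1)
    train, test_observed, test_holdout, truth = mgp.simulate_cohort(cfg)
    return {
        "config": cfg,
        "train": train,
        "test_observed": test_observed,
        "test_holdout": test_holdout,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """Model fitted once on the tiny cohort."""
    return mgp.MultiMeanGP().fit(small_cohort["train"])


def random_hyperparams(rng) -> ModelHyperparams:
    """Random but well-scaled hyperparameters for oracle comparisons."""
    return ModelHyperparams(
        theta0=mgp.KernelParams(rng.uniform(-5, -3), rng.uniform(0.3, 1.3)),
        theta_g=mgp.KernelParams(rng.uniform(-6, -4), rng.uniform(0.0, 1.0)),
        theta_f=mgp.KernelParams(rng.uniform(-7, -4.5), rng.uniform(-0.5, 0.7)),
        noise_variance=float(rng.uniform(5e-4, 5e-3)),
        prior_mean_constant=0.5,
    )


def joint_model_gaussian(grid, blocks, hp):
    """Exhaustive joint Gaussian over (m on grid, all observations).

    ``blocks`` is a list of ``(individual_id, times, values)``; each series
    shares the CpG mean process (prior m0, k_theta0 + k_thetag on ``grid``
    union all observation times is assumed to hold: observation times must
    be contained in ``grid``).  Returns (mean, cov, obs_slices) over the
    stacked vector [m(grid); y_1; ...; y_B].
    """
    grid = np.asarray(grid, float)
    G = grid.size
    Kp = se_kernel(grid, grid, hp.theta0) + se_kernel(grid, grid, hp.theta_g)
    sizes = [len(t) for _, t, _ in blocks]
    N = G + sum(sizes)
    mean = np.full(N, hp.prior_mean_constant)
    cov = np.zeros((N, N))
    cov[:G, :G] = Kp
    Hs = []
    pos = G
    slices = []
    for (_, times, _), n in zip(blocks, sizes):
        H = np.zeros((n, G))
        for r, t in enumerate(times):
            (k,) = np.where(np.isclose(grid, t))
            H[r, k[0]] = 1.0
        Hs.append(H)
        slices.append(slice(pos, pos + n))
        pos += n
    for b, ((ind, times, _), H) in enumerate(zip(blocks, Hs)):
        s = slices[b]
        cov[s, :G] = H @ Kp
        cov[:G, s] = (H @ Kp).T
        for b2, ((ind2, _, _), H2) in enumerate(zip(blocks, Hs)):
            s2 = slices[b2]
            cov[s, s2] = H @ Kp @ H2.T
        tt = np.asarray(times, float)
        own = se_kernel(tt, tt, hp.theta_f_for(ind)) + hp.sigma2_for("") * np.eye(len(tt))
        cov[s, s] += own
    return mean, cov, slices


def condition_explicit(mean, cov, obs_idx, obs_values):
    """Textbook partitioned-Gaussian conditioning with an explicit inverse."""
    obs_idx = np.asarray(obs_idx, int)
    keep = np.setdiff1d(np.arange(mean.size), obs_idx)
    S = cov[np.ix_(obs_idx, obs_idx)]
    Sinv = np.linalg.inv(S)
    cross = cov[np.ix_(keep, obs_idx)]
    cmean = mean[keep] + cross @ Sinv @ (np.asarray(obs_values) - mean[obs_idx])
    ccov = cov[np.ix_(keep, keep)] - cross @ Sinv @ cross.T
    return cmean, ccov
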