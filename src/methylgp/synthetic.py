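"""Synthetic longitudinal methylation cohorts with known ground truth.

Generates data from the additive latent-process model itself — one common
mean trend, one CpG-specific perturbation per CpG, one individual-specific
perturbation per individual, plus i.i.d. noise — on a visit schedule that
emulates a birth-cohort design: four visits near 0.26, 0.76, 4.05 and 6.05
years with small per-individual jitter, so every individual is observed at
their own exact collection ages.

Raw latent sums are mapped into a beta-value band (default [0.05, 0.95]) by
a single global affine rescale, which preserves Gaussianity exactly: the
generated cohort remains model-true with recorded effective hyperparameters,
so parameter-recovery and calibration tests are well-posed.  A logistic
squash is available for realism experiments but breaks model-trueness and
is excluded from recovery assertions.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.special import expit

from .clocks import ClockDefinition
from .gp_core import KernelParams, jittered_cholesky, se_kernel
from .model import MethylationSeriesSet, ModelHyperparams

__all__ = [
    "SimulationConfig",
    "default_true_hyperparams",
    "simulate_cohort",
    "simulate_toy_clock",
]

#: visit schedule (years): cohort means and per-individual jitter SDs
DEFAULT_VISIT_AGES = (0.26, 0.76, 4.05, 6.05)
DEFAULT_VISIT_JITTER_SD = (0.02, 0.02, 0.09, 0.10)


def default_true_hyperparams() -> ModelHyperparams:
    """Generative hyperparameters emulating stable early-life methylation.

    Mean-process and CpG-process kernels share a 3-year lengthscale (they
    enter the model only through their sum); the individual process is
    smaller and faster (1.5 years); noise SD is ~0.03 beta units, typical
    of array-level technical noise.
    """
    return ModelHyperparams(
        theta0=KernelParams(math.log(0.015), math.log(3.0)),
        theta_g=KernelParams(math.log(0.010), math.log(3.0)),
        theta_f=KernelParams(math.log(0.005), math.log(1.5)),
        noise_variance=0.001,
        prior_mean_constant=0.5,
    )


@dataclasses.dataclass
class SimulationConfig:
    """Cohort-simulation settings (counts, visit schedule, truth, seed)."""

    n_train: int = 20
    n_test: int = 10
    n_cpgs: int = 10
    visit_ages: tuple[float, ...] = DEFAULT_VISIT_AGES
    visit_jitter_sd: tuple[float, ...] = DEFAULT_VISIT_JITTER_SD
    true_hyperparams: ModelHyperparams = dataclasses.field(
        default_factory=default_true_hyperparams
    )
    seed: int = 0
    holdout_visits: int = 1
    band: tuple[float, float] = (0.05, 0.95)
    squash: str = "affine"

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_test, self.n_cpgs) < 1:
            raise ValueError("counts must be >= 1")
        ages = np.asarray(self.visit_ages, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("visit ages must be strictly increasing")
        if len(self.visit_jitter_sd) != len(self.visit_ages):
            raise ValueError("one jitter SD per visit is required")
        if any(sd < 0 for sd in self.visit_jitter_sd):
            raise ValueError("jitter SDs must be >= 0")
        if not 0 <= self.holdout_visits < len(self.visit_ages):
            raise ValueError("holdout_visits must leave at least one observed visit")
        if self.squash not in ("affine", "logistic"):
            raise ValueError(f"unknown squash mode {self.squash!r}")


def _draw_gp(rng, times: np.ndarray, params: KernelParams, mean: float = 0.0) -> np.ndarray:
    K = se_kernel(times, times, params)
    L, _ = jittered_cholesky(K)
    return mean + L @ rng.standard_normal(times.size)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MethylationSeriesSet, MethylationSeriesSet, MethylationSeriesSet, dict]:
    """Simulate a train/test cohort from the additive generative process.

    Returns ``(train, test_observed, test_holdout, truth)``.  Test
    individuals' final ``holdout_visits`` visits are moved to the holdout
    set.  ``truth`` records the raw and effective (post-rescale)
    hyperparameters, the affine map, and all latent draws.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    hp = config.true_hyperparams
    n_all = config.n_train + config.n_test
    width = max(3, len(str(n_all)))
    train_ids = [f"tr{k:0{width}d}" for k in range(config.n_train)]
    test_ids = [f"te{k:0{width}d}" for k in range(config.n_test)]
    ids = train_ids + test_ids

    ages = np.asarray(config.visit_ages, dtype=float)
    jit = np.asarray(config.visit_jitter_sd, dtype=float)
    visits = {
        ind: np.maximum(ages + rng.normal(0.0, jit), 0.0) for ind in ids
    }
    union = np.unique(np.concatenate(list(visits.values())))
    pos = {ind: np.searchsorted(union, visits[ind]) for ind in ids}

    cpg_ids = [f"cg{k:07d}" for k in range(config.n_cpgs)]
    mu0 = _draw_gp(rng, union, hp.theta0, mean=hp.prior_mean_constant)
    g = {c: _draw_gp(rng, union, hp.theta_g_for(c)) for c in cpg_ids}
    f = {i: _draw_gp(rng, visits[i], hp.theta_f_for(i)) for i in ids}

    rows_ind, rows_cpg, rows_t, rows_y = [], [], [], []
    for ind in ids:
        p = pos[ind]
        base = mu0[p] + f[ind]
        for c in cpg_ids:
            noise = rng.normal(0.0, math.sqrt(hp.sigma2_for(c)), size=p.size)
            y = base + g[c][p] + noise
            rows_ind.extend([ind] * p.size)
            rows_cpg.extend([c] * p.size)
            rows_t.extend(visits[ind])
            rows_y.append(y)
    y_all = np.concatenate(rows_y)

    lo, hi = config.band
    if config.squash == "affine":
        ymin, ymax = float(y_all.min()), float(y_all.max())
        scale = (hi - lo) / (ymax - ymin) if ymax > ymin else 1.0
        offset = lo - scale * ymin if ymax > ymin else 0.5 - ymin
        y_all = offset + scale * y_all
        effective = ModelHyperparams(
            theta0=KernelParams(
                hp.theta0.log_variance + 2 * math.log(scale), hp.theta0.log_lengthscale
            ),
            theta_g=KernelParams(
                hp.theta_g_for(cpg_ids[0]).log_variance + 2 * math.log(scale),
                hp.theta_g_for(cpg_ids[0]).log_lengthscale,
            ),
            theta_f=KernelParams(
                hp.theta_f_for(ids[0]).log_variance + 2 * math.log(scale),
                hp.theta_f_for(ids[0]).log_lengthscale,
            ),
            noise_variance=hp.sigma2_for(cpg_ids[0]) * scale**2,
            prior_mean_constant=offset + scale * hp.prior_mean_constant,
        )
    else:
        # logistic squash: bounded and realistic but no longer model-true
        y_all = expit(4.0 * (y_all - 0.5))
        scale, offset, effective = float("nan"), float("nan"), None

    frame = pd.DataFrame(
        {
            "individual_id": rows_ind,
            "cpg_id": rows_cpg,
            "age_years": rows_t,
            "beta": np.clip(y_all, 0.0, 1.0),
        }
    )

    n_obs_visits = len(config.visit_ages) - config.holdout_visits
    holdout_ages = {
        ind: set(visits[ind][n_obs_visits:]) for ind in test_ids
    }
    is_test = frame["individual_id"].isin(set(test_ids))
    is_holdout = is_test & frame.apply(
        lambda r: r["age_years"] in holdout_ages.get(r["individual_id"], ()), axis=1
    )
    train = MethylationSeriesSet(frame[~is_test].reset_index(drop=True))
    test_observed = MethylationSeriesSet(
        frame[is_test & ~is_holdout].reset_index(drop=True)
    )
    test_holdout = MethylationSeriesSet(frame[is_holdout].reset_index(drop=True))

    truth = {
        "seed": config.seed,
        "raw_hyperparams": hp.to_dict(),
        "effective_hyperparams": effective.to_dict() if effective else None,
        "affine": {"offset": offset, "scale": scale},
        "squash": config.squash,
        "union_grid": union.tolist(),
        "mu0": mu0.tolist(),
        "g": {c: g[c].tolist() for c in cpg_ids},
        "f": {i: f[i].tolist() for i in ids},
        "visits": {i: visits[i].tolist() for i in ids},
        "train_individuals": train_ids,
        "test_individuals": test_ids,
        "cpg_ids": cpg_ids,
    }
    return train, test_observed, test_holdout, truth


def simulate_toy_clock(
    cpg_ids, scale: float = 0.5, seed: int = 0, adult_age: float = 20.0
) -> ClockDefinition:
    """Random small-coefficient clock for testing the age transform.

    Coefficients are N(0, scale^2); the intercept is solved so that a
    mid-range beta vector (all 0.5) maps to a child-range age of 6 years,
    below ``adult_age`` by construction.
    """
    cpg_ids = list(cpg_ids)
    if not cpg_ids:
        raise ValueError("cpg_ids must be non-empty")
    rng = np.random.default_rng(seed)
    coefs = rng.normal(0.0, scale, size=len(cpg_ids)) if scale > 0 else np.zeros(len(cpg_ids))
    target_lp = math.log((6.0 + 1.0) / (adult_age + 1.0))
    intercept = target_lp - 0.5 * float(np.sum(coefs))
    return ClockDefinition(
        name=f"toy-{seed}",
        intercept=intercept,
        coefficients=dict(zip(cpg_ids, coefs.tolist())),
        adult_age=adult_age,
    )
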