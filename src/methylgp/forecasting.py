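"""Closed-form Gaussian forecasts for individual methylation series.

A forecast for individual ``i`` at CpG ``j`` integrates out the CpG-specific
mean process: the mean hyper-posterior (mean ``m_hat``, covariance ``C_hat``)
is evaluated on the union of observed and target times, the joint covariance
``C_hat + k_thetaf + sigma^2 I`` is formed, and the individual's observed
betas are conditioned on.  With no observations the forecast is the
prior-predictive: mean-process hyper-posterior plus individual-process and
noise variance.  Forecast means are reported as-is (not clamped to [0, 1]);
clamping is available downstream when sampling through clock transforms.

Predictive uncertainty widens away from observed data and reverts to the
mean-process prior far in the future — the characteristic GP behaviour that
makes long-horizon forecasts honest about what they do not know.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .gp_core import GaussianBelief, condition_gaussian, jittered_cholesky, se_kernel
from .model import MethylationSeriesSet, MultiMeanGP

__all__ = [
    "ForecastResult",
    "cpg_mean_posterior",
    "predict_individual",
    "batch_forecast",
    "forecast_frame",
]


@dataclasses.dataclass
class ForecastResult:
    """Gaussian forecast for one individual-CpG series at given target times."""

    individual_id: str
    cpg_id: str
    target_times: np.ndarray
    belief: GaussianBelief

    def __post_init__(self) -> None:
        self.target_times = np.asarray(self.target_times, dtype=float).ravel()
        if self.belief.order != self.target_times.size:
            raise ValueError("belief order must match target_times")


def _check_cpg(model: MultiMeanGP, cpg_id: str) -> None:
    if cpg_id not in model.mean_posteriors_:
        raise KeyError(f"unknown CpG {cpg_id!r}: not present in the trained model")


def _prior_chol(model: MultiMeanGP, cpg_id: str):
    """Cached Cholesky of the mean-process prior on the pooled grid."""
    cache = getattr(model, "_prior_chol_cache", None)
    if cache is None:
        cache = {}
        model._prior_chol_cache = cache
    tg = model.hyperparams_.theta_g_for(cpg_id)
    key = (tg.log_variance, tg.log_lengthscale)
    if key not in cache:
        tau = model.pooled_grid_
        Ktt = se_kernel(tau, tau, model.hyperparams_.theta0) + se_kernel(tau, tau, tg)
        L, _ = jittered_cholesky(Ktt)
        cache[key] = L
    return cache[key]


def cpg_mean_posterior(
    model: MultiMeanGP, cpg_id: str, grid: Sequence[float]
) -> GaussianBelief:
    """Mean-process hyper-posterior for one CpG on an arbitrary time grid.

    Extends the stored pooled-grid posterior by standard GP conditioning of
    the mean process on its grid values (kriging the mean function): exact
    on the training grid, reverting to the prior far from data support.
    """
    _check_cpg(model, cpg_id)
    s = np.asarray(grid, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("grid must be non-empty")
    hp = model.hyperparams_
    tau = model.pooled_grid_
    post = model.mean_posteriors_[cpg_id]
    m0 = model.prior_mean_by_cpg_[cpg_id]
    tg = hp.theta_g_for(cpg_id)
    Kst = se_kernel(s, tau, hp.theta0) + se_kernel(s, tau, tg)
    Kss = se_kernel(s, s, hp.theta0) + se_kernel(s, s, tg)
    L = _prior_chol(model, cpg_id)
    # A = K_st K_tt^-1
    A = linalg.solve_triangular(
        L.T, linalg.solve_triangular(L, Kst.T, lower=True), lower=False
    ).T
    mean = m0 + A @ (post.mean - m0)
    cov = Kss - A @ Kst.T + A @ post.cov @ A.T
    return GaussianBelief(s, mean, 0.5 * (cov + cov.T))


def predict_individual(
    model: MultiMeanGP,
    cpg_id: str,
    observations: Sequence[tuple[float, float]],
    target_times: Sequence[float],
    individual_id: str = "",
) -> ForecastResult:
    """Forecast one individual's series at target times given its history.

    ``observations`` is a (possibly empty) list of ``(age_years, beta)``
    pairs for this individual at this CpG.  The CpG mean process is
    integrated out; the individual's own observations then personalize the
    forecast through the individual-process kernel.
    """
    _check_cpg(model, cpg_id)
    targets = np.asarray(target_times, dtype=float).ravel()
    if targets.size == 0:
        raise ValueError("target_times must be non-empty")
    obs = list(observations)
    obs_t = np.array([t for t, _ in obs], dtype=float)
    obs_y = np.array([y for _, y in obs], dtype=float)
    if obs_y.size and (np.any(obs_y < 0) or np.any(obs_y > 1) or not np.all(np.isfinite(obs_y))):
        raise ValueError("observed betas must lie in [0, 1]")

    hp = model.hyperparams_
    s = np.concatenate([obs_t, targets])
    mp = cpg_mean_posterior(model, cpg_id, s)
    theta_f = hp.theta_f_for(individual_id)
    sigma2 = hp.sigma2_for(cpg_id)
    cov = mp.cov + se_kernel(s, s, theta_f) + sigma2 * np.eye(s.size)
    joint = GaussianBelief(s, mp.mean, cov)
    belief = condition_gaussian(joint, np.arange(obs_t.size), obs_y, 0.0)
    return ForecastResult(individual_id, cpg_id, targets, belief)


def batch_forecast(
    model: MultiMeanGP,
    test_data: MethylationSeriesSet,
    target_times: Sequence[float],
    cpg_panel: Sequence[str],
) -> list[ForecastResult]:
    """One forecast per (test individual x panel CpG) at the target times.

    Individuals with no observations for a CpG receive the prior-predictive
    forecast.  The mean hyper-posterior is extended once per CpG over the
    union of all observation times, so the per-individual conditioning is a
    small dense solve.
    """
    panel = list(cpg_panel)
    if not panel:
        raise ValueError("cpg_panel must be non-empty")
    for cpg in panel:
        _check_cpg(model, cpg)
    targets = np.asarray(target_times, dtype=float).ravel()
    if targets.size == 0:
        raise ValueError("target_times must be non-empty")

    individuals = test_data.individuals
    hp = model.hyperparams_
    frame = test_data.frame
    results: dict[tuple[str, str], ForecastResult] = {}
    for cpg in panel:
        sub = frame[frame["cpg_id"] == cpg]
        series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for ind, grp in sub.groupby("individual_id"):
            order = np.argsort(grp["age_years"].to_numpy())
            series[ind] = (
                grp["age_years"].to_numpy()[order],
                grp["beta"].to_numpy()[order],
            )
        # stacked union: all individuals' observed times, then the targets
        offsets: dict[str, tuple[int, int]] = {}
        pieces = []
        pos = 0
        for ind in individuals:
            t = series.get(ind, (np.empty(0), np.empty(0)))[0]
            offsets[ind] = (pos, pos + t.size)
            pieces.append(t)
            pos += t.size
        s_all = np.concatenate(pieces + [targets]) if pieces else targets
        tgt_idx = np.arange(pos, pos + targets.size)
        mp = cpg_mean_posterior(model, cpg, s_all)
        sigma2 = hp.sigma2_for(cpg)
        for ind in individuals:
            lo, hi = offsets[ind]
            idx = np.concatenate([np.arange(lo, hi), tgt_idx])
            t_i = s_all[idx]
            theta_f = hp.theta_f_for(ind)
            cov = (
                mp.cov[np.ix_(idx, idx)]
                + se_kernel(t_i, t_i, theta_f)
                + sigma2 * np.eye(idx.size)
            )
            joint = GaussianBelief(t_i, mp.mean[idx], cov)
            y = series.get(ind, (np.empty(0), np.empty(0)))[1]
            belief = condition_gaussian(joint, np.arange(hi - lo), y, 0.0)
            results[(ind, cpg)] = ForecastResult(ind, cpg, targets, belief)
    return [results[key] for key in sorted(results)]


def forecast_frame(results: Sequence[ForecastResult]) -> pd.DataFrame:
    """Tabulate forecasts: one row per (individual, CpG, target time)."""
    rows = []
    for r in results:
        sd = r.belief.sd()
        for k, t in enumerate(r.target_times):
            m = r.belief.mean[k]
            rows.append(
                {
                    "individual_id": r.individual_id,
                    "cpg_id": r.cpg_id,
                    "target_time": float(t),
                    "pred_mean": float(m),
                    "pred_sd": float(sd[k]),
                    "ci95_lower": float(m - 1.96 * sd[k]),
                    "ci95_upper": float(m + 1.96 * sd[k]),
                }
            )
    return pd.DataFrame(rows)
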