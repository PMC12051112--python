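"""Additive latent-process model for longitudinal methylation and its EM fit.

A methylation observation for individual ``i`` at CpG ``j`` and age ``t``
(years) is modelled as

    y_ij(t) = mu0(t) + f_i(t) + g_j(t) + eps_ij(t)

with a shared mean process ``mu0 ~ GP(m0, k_theta0)``, an individual-specific
process ``f_i ~ GP(0, k_thetaf)``, a CpG-specific process ``g_j ~ GP(0,
k_thetag)`` and i.i.d. Gaussian noise.  All kernels are squared-exponential.

Only the per-CpG mean ``m_j = mu0 + g_j`` is ever needed for prediction, so
the model tracks its Gaussian hyper-posterior on the pooled grid of observed
times, conditioning each CpG's mean on all series of that CpG.  Individual
series enter with observation covariance ``k_thetaf + sigma^2 I``.

Hyperparameters are estimated by EM: the E-step computes the exact per-CpG
mean hyper-posteriors in closed form; the M-step maximizes the expected
complete-data log-likelihood over log-scale kernel parameters and the noise
variance with a quasi-Newton optimizer.  The fit traces the evidence lower
bound (expected complete-data log-likelihood plus hyper-posterior entropy),
which is non-decreasing because both steps are exact/ascent; this is enforced
as a hard assertion.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize
import pandas as pd
from sklearn.base import BaseEstimator

from .gp_core import GaussianBelief, KernelParams, jittered_cholesky, se_kernel

__all__ = [
    "MethylationSeriesSet",
    "ModelHyperparams",
    "MultiMeanGP",
    "as_series_set",
    "pooled_timestamps",
    "e_step",
    "em_objective",
    "m_step",
    "fit_multimean",
]

logger = logging.getLogger(__name__)

COLUMNS = ("individual_id", "cpg_id", "age_years", "beta")

_LOG2PI = math.log(2.0 * math.pi)
_PARAM_BOUNDS = (-15.0, 6.0)


# ---------------------------------------------------------------------------
# data container


class MethylationSeriesSet:
    """Long-format collection of (individual, CpG, age, beta) observations.

    Wraps a pandas DataFrame with columns ``individual_id, cpg_id,
    age_years, beta``.  Betas are proportions in [0, 1]; ages are
    non-negative decimal years; duplicate (individual, CpG, age) triples
    are rejected loudly rather than averaged.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        frame = frame.loc[:, list(COLUMNS)].copy()
        frame["individual_id"] = frame["individual_id"].astype(str)
        frame["cpg_id"] = frame["cpg_id"].astype(str)
        frame["age_years"] = frame["age_years"].astype(float)
        frame["beta"] = frame["beta"].astype(float)
        if validate:
            if len(frame) == 0:
                raise ValueError("empty input: no methylation records")
            bad = frame.index[
                ~np.isfinite(frame["beta"]) | (frame["beta"] < 0) | (frame["beta"] > 1)
            ]
            if len(bad):
                raise ValueError(
                    f"beta values outside [0, 1] at rows {list(bad[:10])}"
                    + (" ..." if len(bad) > 10 else "")
                )
            bad_t = frame.index[~np.isfinite(frame["age_years"]) | (frame["age_years"] < 0)]
            if len(bad_t):
                raise ValueError(f"invalid ages (must be finite, >= 0) at rows {list(bad_t[:10])}")
            dup = frame.duplicated(subset=["individual_id", "cpg_id", "age_years"])
            if dup.any():
                rows = list(frame.index[dup][:10])
                raise ValueError(
                    f"duplicate (individual, cpg, age) records at rows {rows}"
                    + (" ..." if dup.sum() > 10 else "")
                )
        self._frame = frame

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float]], validate: bool = True
    ) -> "MethylationSeriesSet":
        frame = pd.DataFrame(list(records), columns=list(COLUMNS))
        return cls(frame, validate=validate)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying long-format table (do not mutate)."""
        return self._frame

    @property
    def individuals(self) -> list[str]:
        return sorted(self._frame["individual_id"].unique())

    @property
    def cpgs(self) -> list[str]:
        return sorted(self._frame["cpg_id"].unique())

    @property
    def times(self) -> np.ndarray:
        return np.unique(self._frame["age_years"].to_numpy())

    @property
    def grand_mean(self) -> float:
        return float(self._frame["beta"].mean())

    def series(self, individual_id: str, cpg_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Observed (times, betas) for one individual-CpG couple, time-sorted."""
        sel = self._frame[
            (self._frame["individual_id"] == individual_id)
            & (self._frame["cpg_id"] == cpg_id)
        ]
        order = np.argsort(sel["age_years"].to_numpy())
        return (
            sel["age_years"].to_numpy()[order],
            sel["beta"].to_numpy()[order],
        )

    def filter(
        self,
        individuals: Sequence[str] | None = None,
        cpgs: Sequence[str] | None = None,
    ) -> "MethylationSeriesSet":
        frame = self._frame
        if individuals is not None:
            frame = frame[frame["individual_id"].isin(set(individuals))]
        if cpgs is not None:
            frame = frame[frame["cpg_id"].isin(set(cpgs))]
        return MethylationSeriesSet(frame.reset_index(drop=True), validate=False)

    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:
        return (
            f"MethylationSeriesSet({len(self)} records, "
            f"{len(self.individuals)} individuals, {len(self.cpgs)} CpGs)"
        )


def as_series_set(data) -> MethylationSeriesSet:
    """Coerce a DataFrame or MethylationSeriesSet into a MethylationSeriesSet."""
    if isinstance(data, MethylationSeriesSet):
        return data
    if isinstance(data, pd.DataFrame):
        return MethylationSeriesSet(data)
    raise TypeError(f"cannot interpret {type(data).__name__} as methylation data")


# ---------------------------------------------------------------------------
# hyperparameters


def _theta_lookup(theta, key: str) -> KernelParams:
    if isinstance(theta, KernelParams):
        return theta
    if key in theta:
        return theta[key]
    # unseen entity under per-entity sharing: population-average parameters
    lv = float(np.mean([p.log_variance for p in theta.values()]))
    ll = float(np.mean([p.log_lengthscale for p in theta.values()]))
    return KernelParams(lv, ll)


@dataclasses.dataclass(frozen=True)
class ModelHyperparams:
    """Kernel and noise hyperparameters of the additive model.

    ``theta_g``/``theta_f`` are either a single shared :class:`KernelParams`
    (default) or a mapping keyed by CpG/individual id when per-entity
    parameters are enabled.  ``noise_variance`` is a shared float or a
    per-CpG mapping.  ``prior_mean_constant`` is the constant prior mean
    ``m0`` of the common process.
    """

    theta0: KernelParams
    theta_g: KernelParams | Mapping[str, KernelParams]
    theta_f: KernelParams | Mapping[str, KernelParams]
    noise_variance: float | Mapping[str, float]
    prior_mean_constant: float = 0.0

    def __post_init__(self) -> None:
        sigmas = (
            [self.noise_variance]
            if not isinstance(self.noise_variance, Mapping)
            else list(self.noise_variance.values())
        )
        if any((not math.isfinite(s)) or s < 0 for s in sigmas):
            raise ValueError("noise_variance must be finite and >= 0")
        if not math.isfinite(self.prior_mean_constant):
            raise ValueError("prior_mean_constant must be finite")

    def theta_g_for(self, cpg_id: str) -> KernelParams:
        return _theta_lookup(self.theta_g, cpg_id)

    def theta_f_for(self, individual_id: str) -> KernelParams:
        return _theta_lookup(self.theta_f, individual_id)

    def sigma2_for(self, cpg_id: str) -> float:
        if isinstance(self.noise_variance, Mapping):
            if cpg_id in self.noise_variance:
                return float(self.noise_variance[cpg_id])
            return float(np.mean(list(self.noise_variance.values())))
        return float(self.noise_variance)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def kp(p):
            return {"log_variance": p.log_variance, "log_lengthscale": p.log_lengthscale}

        def theta(t):
            if isinstance(t, KernelParams):
                return kp(t)
            return {k: kp(v) for k, v in t.items()}

        return {
            "theta0": kp(self.theta0),
            "theta_g": theta(self.theta_g),
            "theta_f": theta(self.theta_f),
            "noise_variance": (
                dict(self.noise_variance)
                if isinstance(self.noise_variance, Mapping)
                else self.noise_variance
            ),
            "prior_mean_constant": self.prior_mean_constant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelHyperparams":
        def kp(e):
            return KernelParams(e["log_variance"], e["log_lengthscale"])

        def theta(e):
            if "log_variance" in e:
                return kp(e)
            return {k: kp(v) for k, v in e.items()}

        nv = d["noise_variance"]
        return cls(
            theta0=kp(d["theta0"]),
            theta_g=theta(d["theta_g"]),
            theta_f=theta(d["theta_f"]),
            noise_variance=dict(nv) if isinstance(nv, dict) else float(nv),
            prior_mean_constant=float(d["prior_mean_constant"]),
        )


# ---------------------------------------------------------------------------
# grid and fit index


def pooled_timestamps(
    data: MethylationSeriesSet, extra: Sequence[float] | None = None
) -> np.ndarray:
    """Sorted union of all distinct observation times plus extra times."""
    times = data.frame["age_years"].to_numpy()
    if extra is not None and len(extra):
        times = np.concatenate([times, np.asarray(extra, dtype=float)])
    return np.unique(times)


class _FitIndex:
    """Pre-indexed view of the data on a fixed grid, reused across EM steps."""

    def __init__(self, data: MethylationSeriesSet, grid: np.ndarray):
        self.grid = np.asarray(grid, dtype=float)
        frame = data.frame
        idx_all = np.searchsorted(self.grid, frame["age_years"].to_numpy())
        if (
            idx_all.max(initial=-1) >= self.grid.size
            or not np.allclose(self.grid[idx_all], frame["age_years"].to_numpy())
        ):
            raise ValueError("grid does not cover all observed times")
        self.cpgs = sorted(frame["cpg_id"].unique())
        self.individuals = sorted(frame["individual_id"].unique())
        self.blocks: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {
            c: [] for c in self.cpgs
        }
        work = frame.assign(_gidx=idx_all)
        for (cpg, ind), grp in work.groupby(["cpg_id", "individual_id"], sort=True):
            order = np.argsort(grp["_gidx"].to_numpy())
            self.blocks[cpg].append(
                (
                    ind,
                    grp["_gidx"].to_numpy()[order],
                    grp["beta"].to_numpy()[order],
                )
            )


class _BlockCache:
    """Per-hyperparameter cache of small observation-block factorizations."""

    def __init__(self, grid: np.ndarray):
        self.grid = grid
        self._store: dict[tuple, tuple[np.ndarray, float]] = {}

    def get(self, idx: np.ndarray, theta_f: KernelParams, sigma2: float):
        key = (idx.tobytes(), theta_f.log_variance, theta_f.log_lengthscale, sigma2)
        hit = self._store.get(key)
        if hit is None:
            t = self.grid[idx]
            Psi = se_kernel(t, t, theta_f) + sigma2 * np.eye(idx.size)
            L, _ = jittered_cholesky(Psi)
            inv = linalg.solve_triangular(
                L.T, linalg.solve_triangular(L, np.eye(idx.size), lower=True), lower=False
            )
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            hit = (inv, logdet)
            self._store[key] = hit
        return hit


def _prior_factor(grid: np.ndarray, hp: ModelHyperparams, cpg: str, cache: dict):
    """Jittered prior k_theta0 + k_thetag with its inverse and log-determinant.

    Returns ``(Kp, inv, logdet)`` for the nugget-stabilized prior actually
    used by both the E-step and the objective, so the two stay consistent.
    """
    tg = hp.theta_g_for(cpg)
    key = (tg.log_variance, tg.log_lengthscale)
    hit = cache.get(key)
    if hit is None:
        Kp = se_kernel(grid, grid, hp.theta0) + se_kernel(grid, grid, tg)
        L, jitter = jittered_cholesky(Kp)
        Kp = Kp + jitter * np.eye(grid.size)
        eye = np.eye(grid.size)
        inv = linalg.solve_triangular(
            L.T, linalg.solve_triangular(L, eye, lower=True), lower=False
        )
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        hit = (Kp, 0.5 * (inv + inv.T), logdet)
        cache[key] = hit
    return hit


# ---------------------------------------------------------------------------
# E-step


def _m0_map(index: _FitIndex, hp: ModelHyperparams, m0_by_cpg=None) -> dict[str, float]:
    if m0_by_cpg is None:
        return {c: hp.prior_mean_constant for c in index.cpgs}
    return {c: float(m0_by_cpg.get(c, hp.prior_mean_constant)) for c in index.cpgs}


def _e_step_full(
    index: _FitIndex, hp: ModelHyperparams, m0_by_cpg=None
) -> tuple[dict[str, GaussianBelief], dict[str, float]]:
    """Exact per-CpG hyper-posteriors plus their covariance log-determinants.

    Works in the conditioning (covariance) form: only the observation
    covariance ``S = Kp[obs, obs] + blockdiag(k_thetaf + sigma^2 I)`` is
    factorized, which stays well-conditioned because of the noise floor,
    unlike the near-singular prior precision.  The posterior covariance
    log-determinant comes from the Gaussian conditioning identity
    ``logdet C = logdet Kp + logdet D - logdet S`` (D the block-diagonal
    observation noise), avoiding a factorization of the tiny-eigenvalue
    posterior itself.
    """
    grid = index.grid
    m0 = _m0_map(index, hp, m0_by_cpg)
    prior_cache: dict = {}
    out: dict[str, GaussianBelief] = {}
    logdets: dict[str, float] = {}
    for cpg in index.cpgs:
        Kp, _, logdetKp = _prior_factor(grid, hp, cpg, prior_cache)
        sigma2 = hp.sigma2_for(cpg)
        blocks = index.blocks[cpg]
        if not blocks:
            out[cpg] = GaussianBelief(grid, np.full(grid.size, m0[cpg]), Kp)
            logdets[cpg] = logdetKp
            continue
        obs_idx = np.concatenate([idx for _, idx, _ in blocks])
        y = np.concatenate([yv for _, _, yv in blocks])
        S = Kp[np.ix_(obs_idx, obs_idx)].copy()
        logdetD = 0.0
        pos = 0
        for ind, idx, _ in blocks:
            t = grid[idx]
            D = se_kernel(t, t, hp.theta_f_for(ind)) + sigma2 * np.eye(idx.size)
            S[pos : pos + idx.size, pos : pos + idx.size] += D
            Ld, _ = jittered_cholesky(D)
            logdetD += 2.0 * float(np.sum(np.log(np.diag(Ld))))
            pos += idx.size
        Ls, _ = jittered_cholesky(S)
        logdetS = 2.0 * float(np.sum(np.log(np.diag(Ls))))
        cross = Kp[:, obs_idx]
        # gain = Kp[:, obs] S^-1
        gain = linalg.solve_triangular(
            Ls.T, linalg.solve_triangular(Ls, cross.T, lower=True), lower=False
        ).T
        mean = m0[cpg] + gain @ (y - m0[cpg])
        C = Kp - gain @ cross.T
        out[cpg] = GaussianBelief(grid, mean, 0.5 * (C + C.T))
        logdets[cpg] = logdetKp + logdetD - logdetS
    return out, logdets


def _e_step(
    index: _FitIndex, hp: ModelHyperparams, m0_by_cpg=None
) -> dict[str, GaussianBelief]:
    return _e_step_full(index, hp, m0_by_cpg)[0]


def e_step(
    data: MethylationSeriesSet, hp: ModelHyperparams, grid: Sequence[float]
) -> dict[str, GaussianBelief]:
    """Per-CpG Gaussian hyper-posterior of the mean process m_j = mu0 + g_j.

    Conditions the prior ``GP(m0, k_theta0 + k_thetag)`` evaluated on
    ``grid`` on all series of each CpG; each individual's series enters
    with observation covariance ``k_thetaf + sigma^2 I`` at its observed
    times.  A CpG with no observations keeps its prior.
    """
    index = _FitIndex(data, np.asarray(grid, dtype=float))
    return _e_step(index, hp)


# ---------------------------------------------------------------------------
# objective


def _expected_loglik(
    index: _FitIndex,
    hp: ModelHyperparams,
    posts: Mapping[str, GaussianBelief],
    m0_by_cpg=None,
) -> float:
    """Expected complete-data log-likelihood under the hyper-posteriors."""
    grid = index.grid
    G = grid.size
    m0 = _m0_map(index, hp, m0_by_cpg)
    prior_cache: dict = {}
    blocks = _BlockCache(grid)
    total = 0.0
    for cpg in index.cpgs:
        post = posts[cpg]
        if post.order != G:
            raise ValueError(f"posterior for {cpg} has order {post.order}, grid has {G}")
        _, Kp_inv, logdetKp = _prior_factor(grid, hp, cpg, prior_cache)
        dm = post.mean - m0[cpg]
        total += -0.5 * (
            G * _LOG2PI
            + logdetKp
            + float(dm @ (Kp_inv @ dm))
            + float(np.sum(Kp_inv * post.cov))
        )
        sigma2 = hp.sigma2_for(cpg)
        for ind, idx, y in index.blocks[cpg]:
            inv, logdet = blocks.get(idx, hp.theta_f_for(ind), sigma2)
            r = y - post.mean[idx]
            Csub = post.cov[np.ix_(idx, idx)]
            total += -0.5 * (
                idx.size * _LOG2PI
                + logdet
                + float(r @ (inv @ r))
                + float(np.sum(inv * Csub))
            )
    return total


def em_objective(
    data: MethylationSeriesSet,
    hp: ModelHyperparams,
    mean_posteriors: Mapping[str, GaussianBelief],
) -> float:
    """Expected complete-data log-likelihood given fixed mean hyper-posteriors.

    Sum over CpGs of the expected Gaussian data log-likelihood (quadratic
    plus trace-of-covariances term) and the expected prior log-density of
    the mean process.
    """
    grid = next(iter(mean_posteriors.values())).grid
    index = _FitIndex(data, grid)
    return _expected_loglik(index, hp, mean_posteriors)


def _entropy(
    posts: Mapping[str, GaussianBelief], logdets: Mapping[str, float] | None = None
) -> float:
    total = 0.0
    for cpg, post in posts.items():
        if logdets is not None and cpg in logdets:
            logdet = logdets[cpg]
        else:
            L, _ = jittered_cholesky(post.cov)
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        total += 0.5 * (post.order * (_LOG2PI + 1.0) + logdet)
    return total


def _elbo(index, hp, posts, m0_by_cpg=None, logdets=None) -> float:
    return _expected_loglik(index, hp, posts, m0_by_cpg) + _entropy(posts, logdets)


# ---------------------------------------------------------------------------
# M-step


def _pack(hp: ModelHyperparams, cpgs: list[str], individuals: list[str]) -> np.ndarray:
    v = [hp.theta0.log_variance, hp.theta0.log_lengthscale]
    if isinstance(hp.theta_g, KernelParams):
        v += [hp.theta_g.log_variance, hp.theta_g.log_lengthscale]
    else:
        for c in cpgs:
            p = hp.theta_g_for(c)
            v += [p.log_variance, p.log_lengthscale]
    if isinstance(hp.theta_f, KernelParams):
        v += [hp.theta_f.log_variance, hp.theta_f.log_lengthscale]
    else:
        for i in individuals:
            p = hp.theta_f_for(i)
            v += [p.log_variance, p.log_lengthscale]
    if isinstance(hp.noise_variance, Mapping):
        v += [math.log(max(hp.sigma2_for(c), 1e-12)) for c in cpgs]
    else:
        v += [math.log(max(float(hp.noise_variance), 1e-12))]
    return np.array(v, dtype=float)


def _unpack(
    vec: np.ndarray, template: ModelHyperparams, cpgs: list[str], individuals: list[str]
) -> ModelHyperparams:
    pos = 0

    def take(n):
        nonlocal pos
        out = vec[pos : pos + n]
        pos += n
        return out

    theta0 = KernelParams(*take(2))
    if isinstance(template.theta_g, KernelParams):
        theta_g: KernelParams | dict = KernelParams(*take(2))
    else:
        theta_g = {c: KernelParams(*take(2)) for c in cpgs}
    if isinstance(template.theta_f, KernelParams):
        theta_f: KernelParams | dict = KernelParams(*take(2))
    else:
        theta_f = {i: KernelParams(*take(2)) for i in individuals}
    if isinstance(template.noise_variance, Mapping):
        noise: float | dict = {c: math.exp(float(take(1)[0])) for c in cpgs}
    else:
        noise = math.exp(float(take(1)[0]))
    return ModelHyperparams(
        theta0, theta_g, theta_f, noise, template.prior_mean_constant
    )


def _m_step(
    index: _FitIndex,
    posts: Mapping[str, GaussianBelief],
    hp_init: ModelHyperparams,
    maxiter: int = 20,
    m0_by_cpg=None,
) -> ModelHyperparams:
    x0 = _pack(hp_init, index.cpgs, index.individuals)

    def negQ(x):
        try:
            hp = _unpack(x, hp_init, index.cpgs, index.individuals)
            val = _expected_loglik(index, hp, posts, m0_by_cpg)
        except (linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e12
        if not math.isfinite(val):
            return 1e12
        return -val

    q0 = -negQ(x0)
    # finite-difference step sized for log-scale parameters: the default
    # sqrt(machine-eps) step is drowned out by factorization jitter noise
    res = optimize.minimize(
        negQ,
        x0,
        method="L-BFGS-B",
        bounds=[_PARAM_BOUNDS] * x0.size,
        options={"maxiter": maxiter, "eps": 1e-5},
    )
    q1 = -float(res.fun)
    if q1 < q0 - 1e-9:
        # keep the ascent guarantee; warn only on a material failure (a
        # sub-tolerance decrease just means we were already at the optimum)
        if q1 < q0 - 1e-6 * (1.0 + abs(q0)):
            warnings.warn(
                "M-step optimizer failed to improve the objective; keeping "
                "previous hyperparameters",
                RuntimeWarning,
            )
        return hp_init
    return _unpack(res.x, hp_init, index.cpgs, index.individuals)


def m_step(
    data: MethylationSeriesSet,
    mean_posteriors: Mapping[str, GaussianBelief],
    hp_init: ModelHyperparams,
    maxiter: int = 20,
) -> ModelHyperparams:
    """Maximize the expected complete-data log-likelihood over hyperparameters.

    Quasi-Newton (L-BFGS-B) ascent on log-scale parameters starting at
    ``hp_init``; returns ``hp_init`` with a warning if the optimizer fails
    to improve the objective.
    """
    grid = next(iter(mean_posteriors.values())).grid
    index = _FitIndex(data, grid)
    return _m_step(index, mean_posteriors, hp_init, maxiter=maxiter)


# ---------------------------------------------------------------------------
# estimator


class MultiMeanGP(BaseEstimator):
    """Multi-mean Gaussian process model for longitudinal methylation cohorts.

    Fits the additive model ``y_ij = mu0 + f_i + g_j + eps`` by EM,
    exposing per-CpG mean-process hyper-posteriors for downstream
    forecasting.  Follows scikit-learn estimator conventions; ``fit``
    accepts a long-format DataFrame (columns ``individual_id, cpg_id,
    age_years, beta``) or a :class:`MethylationSeriesSet`.

    Parameters
    ----------
    sharing : {"common", "specific"}
        "common" shares one theta_f across individuals and one theta_g
        across CpGs (default, matching cohort-scale training); "specific"
        gives each entity its own kernel parameters (small cohorts only —
        the M-step dimension grows with the cohort).
    tol : float
        Relative objective-change threshold for EM convergence.
    max_iter : int
        Maximum number of EM iterations.
    prior_mean : {"grand", "per_cpg"} or float
        Constant prior mean m0 of the mean process: the grand mean of
        training betas, a per-CpG empirical mean, or an explicit constant.
    noise_mode : {"shared", "per_cpg"}
        One shared noise variance (default; per-series noise is not
        identifiable from four visits) or one per CpG.
    m_step_maxiter : int
        L-BFGS-B iteration cap inside each M-step.
    init_lengthscale : float
        Initial kernel lengthscale in years for all processes.
    extra_times : sequence of float, optional
        Additional times to include in the pooled grid (e.g. planned
        forecast ages).

    Attributes
    ----------
    hyperparams_ : ModelHyperparams
        Estimated kernel/noise hyperparameters.
    pooled_grid_ : ndarray
        Sorted union of training times (plus ``extra_times``).
    mean_posteriors_ : dict[str, GaussianBelief]
        Per-CpG hyper-posterior of the mean process on ``pooled_grid_``.
    prior_mean_by_cpg_ : dict[str, float]
        Constant prior mean used for each CpG.
    objective_trace_ : ndarray
        ELBO after initialization and after each EM iteration
        (non-decreasing).
    n_iter_, converged_, training_summary_
        EM iteration count, convergence flag, and a summary dict.
    """

    def __init__(
        self,
        sharing: str = "common",
        tol: float = 1e-3,
        max_iter: int = 25,
        prior_mean="grand",
        noise_mode: str = "shared",
        m_step_maxiter: int = 20,
        init_lengthscale: float = 2.0,
        extra_times=None,
    ):
        self.sharing = sharing
        self.tol = tol
        self.max_iter = max_iter
        self.prior_mean = prior_mean
        self.noise_mode = noise_mode
        self.m_step_maxiter = m_step_maxiter
        self.init_lengthscale = init_lengthscale
        self.extra_times = extra_times

    # -- fitting -----------------------------------------------------------

    def _initial_hyperparams(
        self, data: MethylationSeriesSet, cpgs: list[str], individuals: list[str]
    ) -> ModelHyperparams:
        emp_var = max(float(data.frame["beta"].var()), 1e-6)
        lv = math.log(emp_var)
        ll = math.log(self.init_lengthscale)
        kp = KernelParams(lv, ll)
        theta_g = kp if self.sharing == "common" else {c: kp for c in cpgs}
        theta_f = kp if self.sharing == "common" else {i: kp for i in individuals}
        noise = 0.1 * emp_var
        if self.noise_mode == "per_cpg":
            noise = {c: 0.1 * emp_var for c in cpgs}
        m0 = self._grand_m0(data)
        return ModelHyperparams(kp, theta_g, theta_f, noise, m0)

    def _grand_m0(self, data: MethylationSeriesSet) -> float:
        if isinstance(self.prior_mean, (int, float)) and not isinstance(self.prior_mean, bool):
            return float(self.prior_mean)
        return data.grand_mean

    def _m0_by_cpg(self, data: MethylationSeriesSet, cpgs: list[str]) -> dict[str, float]:
        if self.prior_mean == "per_cpg":
            means = data.frame.groupby("cpg_id")["beta"].mean()
            return {c: float(means[c]) for c in cpgs}
        m0 = self._grand_m0(data)
        return {c: m0 for c in cpgs}

    def fit(self, data, y=None) -> "MultiMeanGP":
        """Estimate hyperparameters and per-CpG mean hyper-posteriors by EM."""
        if self.sharing not in ("common", "specific"):
            raise ValueError(f"unknown sharing mode {self.sharing!r}")
        if self.noise_mode not in ("shared", "per_cpg"):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")
        data = as_series_set(data)
        if len(data.individuals) < 2:
            raise ValueError("at least 2 individuals are required")
        if data.times.size < 2:
            raise ValueError("fewer than 2 distinct timepoints: no temporal signal to fit")

        grid = pooled_timestamps(data, self.extra_times)
        index = _FitIndex(data, grid)
        m0_by_cpg = self._m0_by_cpg(data, index.cpgs)
        hp = self._initial_hyperparams(data, index.cpgs, index.individuals)

        posts, logdets = _e_step_full(index, hp, m0_by_cpg)
        elbo = _elbo(index, hp, posts, m0_by_cpg, logdets)
        trace = [elbo]
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            hp = _m_step(index, posts, hp, maxiter=self.m_step_maxiter, m0_by_cpg=m0_by_cpg)
            posts, logdets = _e_step_full(index, hp, m0_by_cpg)
            new = _elbo(index, hp, posts, m0_by_cpg, logdets)
            if new < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
                raise RuntimeError(
                    f"EM objective decreased at iteration {n_iter}: "
                    f"{trace[-1]:.6f} -> {new:.6f}"
                )
            trace.append(new)
            rel = abs(new - trace[-2]) / (1.0 + abs(trace[-2]))
            if rel < self.tol:
                converged = True
                break
        logger.info(
            "EM finished after %d iterations (converged=%s, objective=%.4f)",
            n_iter,
            converged,
            trace[-1],
        )

        self.hyperparams_ = dataclasses.replace(
            hp, prior_mean_constant=self._grand_m0(data)
        )
        self.pooled_grid_ = grid
        self.mean_posteriors_ = posts
        self.prior_mean_by_cpg_ = m0_by_cpg
        self.objective_trace_ = np.array(trace)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.training_summary_ = {
            "n_iterations": n_iter,
            "final_objective": float(trace[-1]),
            "converged": converged,
        }
        return self

    @property
    def cpgs_(self) -> list[str]:
        return sorted(self.mean_posteriors_.keys())

    # -- prediction (thin wrappers over the forecasting module) ------------

    def predict_series(self, cpg_id: str, observations, target_times):
        """Gaussian forecast for one individual-CpG series; see
        :func:`methylgp.forecasting.predict_individual`."""
        from . import forecasting

        return forecasting.predict_individual(
            self, cpg_id, observations, target_times
        )

    def predict(self, data, target_times, cpg_panel=None):
        """Batch forecasts for every (individual, panel CpG) pair; see
        :func:`methylgp.forecasting.batch_forecast`."""
        from . import forecasting

        if cpg_panel is None:
            cpg_panel = self.cpgs_
        return forecasting.batch_forecast(self, as_series_set(data), target_times, cpg_panel)

    # -- serialization ------------------------------------------------------

    def to_payload(self) -> dict:
        """JSON-serializable snapshot of the fitted model."""
        if not hasattr(self, "mean_posteriors_"):
            raise ValueError("model is not fitted")
        return {
            "params": self.get_params(),
            "hyperparams": self.hyperparams_.to_dict(),
            "pooled_grid": self.pooled_grid_.tolist(),
            "prior_mean_by_cpg": self.prior_mean_by_cpg_,
            "mean_posteriors": {
                c: {"mean": b.mean.tolist(), "cov": b.cov.tolist()}
                for c, b in self.mean_posteriors_.items()
            },
            "objective_trace": self.objective_trace_.tolist(),
            "training_summary": self.training_summary_,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "MultiMeanGP":
        params = dict(payload.get("params", {}))
        if isinstance(params.get("extra_times"), list):
            params["extra_times"] = tuple(params["extra_times"])
        model = cls(**params)
        model.hyperparams_ = ModelHyperparams.from_dict(payload["hyperparams"])
        model.pooled_grid_ = np.asarray(payload["pooled_grid"], dtype=float)
        model.prior_mean_by_cpg_ = {
            k: float(v) for k, v in payload["prior_mean_by_cpg"].items()
        }
        grid = model.pooled_grid_
        model.mean_posteriors_ = {
            c: GaussianBelief(grid, np.asarray(b["mean"]), np.asarray(b["cov"]))
            for c, b in payload["mean_posteriors"].items()
        }
        model.objective_trace_ = np.asarray(payload["objective_trace"], dtype=float)
        model.training_summary_ = payload["training_summary"]
        model.n_iter_ = int(model.training_summary_["n_iterations"])
        model.converged_ = bool(model.training_summary_["converged"])
        return model


def fit_multimean(data, **config) -> MultiMeanGP:
    """Functional wrapper: fit a :class:`MultiMeanGP` with the given config."""
    return MultiMeanGP(**config).fit(data)
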