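"""Dense Gaussian-process numerics on small time grids.

Kernel evaluation and numerically stable multivariate-Gaussian algebra
(conditioning, log-density, sampling) shared by the whole package.  Time
is always measured in decimal years; methylation signals are beta values,
so kernel variances carry beta-squared units.

All hyperparameters live on the log scale so that downstream optimization
is unconstrained.  Factorizations are lower-triangular Cholesky with an
escalating diagonal jitter: four-visit grids under smooth kernels are
routinely near-singular.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "KernelParams",
    "GaussianBelief",
    "se_kernel",
    "jittered_cholesky",
    "condition_gaussian",
    "gaussian_logpdf",
    "sample_gaussian",
]

#: initial diagonal jitter, relative to the mean diagonal entry
JITTER_START = 1e-8
#: jitter ceiling; beyond this the matrix is reported as singular
JITTER_MAX = 1e-4


@dataclasses.dataclass(frozen=True)
class KernelParams:
    """Squared-exponential kernel hyperparameters on the log scale.

    Parameters
    ----------
    log_variance
        Log of the signal variance (beta^2 units).
    log_lengthscale
        Log of the lengthscale (years).
    """

    log_variance: float
    log_lengthscale: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.log_variance) and math.isfinite(self.log_lengthscale)):
            raise ValueError("kernel hyperparameters must be finite")

    @property
    def variance(self) -> float:
        return math.exp(self.log_variance)

    @property
    def lengthscale(self) -> float:
        return math.exp(self.log_lengthscale)


def se_kernel(t1: Sequence[float], t2: Sequence[float], params: KernelParams) -> np.ndarray:
    """Squared-exponential (RBF) kernel matrix between two time vectors.

    ``K[a, b] = variance * exp(-(t1[a] - t2[b])^2 / (2 * lengthscale^2))``.
    """
    a = np.asarray(t1, dtype=float).ravel()
    b = np.asarray(t2, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("se_kernel requires non-empty time vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("se_kernel requires finite time vectors")
    d = a[:, None] - b[None, :]
    ell = params.lengthscale
    return params.variance * np.exp(-0.5 * (d / ell) ** 2)


@dataclasses.dataclass
class GaussianBelief:
    """A finite-dimensional Gaussian over a time grid.

    Represents either a mean-process hyper-posterior or an individual
    forecast: ``mean[k]`` and ``cov[k, k]`` describe the belief about the
    signal at ``grid[k]`` years.  The covariance is symmetrized on
    construction; a materially asymmetric input is rejected.
    """

    grid: np.ndarray
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).ravel()
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        n = self.grid.size
        if self.mean.size != n or cov.shape != (n, n):
            raise ValueError(
                f"inconsistent belief dimensions: grid {n}, mean {self.mean.size}, cov {cov.shape}"
            )
        scale = max(1.0, float(np.max(np.abs(cov))) if cov.size else 1.0)
        if cov.size and np.max(np.abs(cov - cov.T)) > 1e-10 * scale:
            raise ValueError("covariance is not symmetric within tolerance")
        self.cov = 0.5 * (cov + cov.T)

    @property
    def order(self) -> int:
        return self.grid.size

    def sd(self) -> np.ndarray:
        """Marginal standard deviations (negative round-off clipped to 0)."""
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def jittered_cholesky(cov: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of ``cov`` with escalating diagonal jitter.

    Jitter starts at ``JITTER_START * mean(diag)`` and is multiplied by 10
    on failure up to ``JITTER_MAX * mean(diag)``, after which a LinAlgError
    with a diagnostic is raised.  Returns ``(L, jitter_used)``.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    diag_mean = float(np.mean(np.diag(cov))) if n else 0.0
    scale = diag_mean if diag_mean > 0 else 1.0
    rel = JITTER_START
    while True:
        try:
            L = linalg.cholesky(cov + rel * scale * np.eye(n), lower=True)
            return L, rel * scale
        except linalg.LinAlgError:
            rel *= 10.0
            if rel > JITTER_MAX:
                raise linalg.LinAlgError(
                    "covariance not positive definite even after jitter "
                    f"{JITTER_MAX * scale:.3e} (order {n}, mean diagonal {diag_mean:.3e})"
                ) from None


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    y = linalg.solve_triangular(L, b, lower=True)
    return linalg.solve_triangular(L.T, y, lower=False)


def condition_gaussian(
    joint: GaussianBelief,
    observed_idx: Sequence[int],
    observed_values: Sequence[float],
    noise_variance: float,
) -> GaussianBelief:
    """Condition a joint Gaussian on noisy observations of a subset of indices.

    The observation covariance is the corresponding block of ``joint.cov``
    plus ``noise_variance * I``.  Returns the conditional belief over the
    complement indices (original order preserved).  An empty index set
    returns the joint unchanged.
    """
    idx = np.asarray(observed_idx, dtype=int).ravel()
    if idx.size == 0:
        return joint
    if noise_variance < 0:
        raise ValueError("noise_variance must be non-negative")
    values = np.asarray(observed_values, dtype=float).ravel()
    if values.size != idx.size:
        raise ValueError("observed_values length must match observed_idx")
    n = joint.order
    if idx.min() < 0 or idx.max() >= n:
        raise IndexError("observed_idx out of range")
    keep = np.setdiff1d(np.arange(n), idx, assume_unique=False)
    S = joint.cov[np.ix_(idx, idx)] + noise_variance * np.eye(idx.size)
    cross = joint.cov[np.ix_(keep, idx)]
    try:
        L, _ = jittered_cholesky(S)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(f"singular observation covariance: {exc}") from exc
    gain = _chol_solve(L, cross.T).T  # cross @ S^-1
    mean = joint.mean[keep] + gain @ (values - joint.mean[idx])
    cov = joint.cov[np.ix_(keep, keep)] - gain @ cross.T
    return GaussianBelief(joint.grid[keep], mean, 0.5 * (cov + cov.T))


def gaussian_logpdf(x: Sequence[float], belief: GaussianBelief) -> float:
    """Multivariate normal log-density of ``x`` under ``belief``.

    Computed through the jittered Cholesky factor (log-determinant as the
    sum of log diagonal entries), never via an explicit inverse.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != belief.order:
        raise ValueError(f"dimension mismatch: x has {x.size}, belief order {belief.order}")
    L, _ = jittered_cholesky(belief.cov)
    resid = linalg.solve_triangular(L, x - belief.mean, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (x.size * math.log(2.0 * math.pi) + logdet + float(resid @ resid))


def sample_gaussian(
    belief: GaussianBelief, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` samples from ``belief``; shape ``(n, order)``.

    Uses an eigendecomposition with small negative eigenvalues (round-off)
    clipped to zero, so degenerate beliefs sample exactly at their mean.
    Eigenvalues below ``-1e-8 * trace / order`` indicate a genuinely
    indefinite covariance and raise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, V = linalg.eigh(belief.cov)
    tol = 1e-8 * max(float(np.trace(belief.cov)) / belief.order, 1e-300)
    if w.min() < -tol:
        raise linalg.LinAlgError(
            f"covariance indefinite beyond jitter tolerance (min eigenvalue {w.min():.3e})"
        )
    root = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, belief.order))
    return belief.mean[None, :] + z @ root.T
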