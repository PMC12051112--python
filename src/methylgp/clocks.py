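"""Epigenetic clocks: age transforms, Monte-Carlo propagation, acceleration.

An epigenetic clock is a published elastic-net signature: a coefficient per
CpG plus an intercept, combined through the child-range inverse of the
log-linear age transform,

    age = (adult_age + 1) * exp(intercept + c^T x) - 1,

with ``adult_age = 20`` by convention, so a zero linear predictor maps to
age 20 exactly.  This form is valid for ages at or below ``adult_age`` (the
cohort regime); the piecewise-linear adult branch of the original transform
is deliberately not implemented.

When the methylation vector ``x`` is a Gaussian forecast rather than a
measurement, the full uncertainty is propagated by sampling beta vectors
from the per-CpG predictive distributions (independently across CpGs, as
induced by the additive model once the shared mean is integrated out),
mapping each sample through the clock, and reporting the empirical age
distribution.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClockDefinition",
    "AgeDistribution",
    "epigenetic_age",
    "epigenetic_age_mc",
    "age_acceleration",
    "load_clock",
    "write_clock",
]

logger = logging.getLogger(__name__)

INTERCEPT_ID = "(Intercept)"


@dataclasses.dataclass(frozen=True)
class ClockDefinition:
    """An epigenetic clock: intercept, CpG coefficients and age constant."""

    name: str
    intercept: float
    coefficients: Mapping[str, float]
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.adult_age <= 0:
            raise ValueError("adult_age must be > 0")
        if not math.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        if any(not math.isfinite(v) for v in self.coefficients.values()):
            raise ValueError("clock coefficients must be finite")

    @property
    def cpgs(self) -> list[str]:
        return list(self.coefficients.keys())


@dataclasses.dataclass
class AgeDistribution:
    """Empirical epigenetic-age distribution from Monte-Carlo propagation."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size == 0:
            raise ValueError("empty sample set")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if self.n > 1 else 0.0

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.samples, [2.5, 97.5])
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.ci95
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ci95_lower": lo,
            "ci95_upper": hi,
            "n": self.n,
        }


def _age_transform(linear_predictor: np.ndarray | float, adult_age: float):
    return (adult_age + 1.0) * np.exp(linear_predictor) - 1.0


def epigenetic_age(x: Mapping[str, float], clock: ClockDefinition) -> float:
    """Plug-in epigenetic age of a methylation vector under a clock.

    ``x`` maps CpG id to beta value and must cover every clock CpG.
    """
    missing = [c for c in clock.coefficients if c not in x]
    if missing:
        raise KeyError(
            f"methylation vector misses {len(missing)} clock CpGs: {missing[:5]}"
            + (" ..." if len(missing) > 5 else "")
        )
    lp = clock.intercept + sum(c * float(x[k]) for k, c in clock.coefficients.items())
    return float(_age_transform(lp, clock.adult_age))


def epigenetic_age_mc(
    forecasts: Sequence,
    clock: ClockDefinition,
    n: int = 10_000,
    seed: int | np.random.Generator = 0,
    clamp: bool = False,
) -> AgeDistribution:
    """Propagate forecast uncertainty through a clock by Monte Carlo.

    ``forecasts`` are single-time :class:`~methylgp.forecasting.ForecastResult`
    objects for one individual, covering all clock CpGs at the same target
    time.  ``n`` independent beta vectors are sampled (CpGs independently),
    optionally clamped to [0, 1], and mapped through the age transform.
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    by_cpg = {}
    times = []
    for fr in forecasts:
        if fr.target_times.size != 1:
            raise ValueError("each forecast must be at a single target time")
        by_cpg[fr.cpg_id] = fr
        times.append(float(fr.target_times[0]))
    missing = [c for c in clock.coefficients if c not in by_cpg]
    if missing:
        raise KeyError(
            f"forecasts miss {len(missing)} clock CpGs: {missing[:5]}"
            + (" ..." if len(missing) > 5 else "")
        )
    if times and not np.allclose(times, times[0], atol=1e-9):
        raise ValueError("all forecasts must share the same target time")

    cpgs = clock.cpgs
    coef = np.array([clock.coefficients[c] for c in cpgs])
    mean = np.array([by_cpg[c].belief.mean[0] for c in cpgs])
    sd = np.array([by_cpg[c].belief.sd()[0] for c in cpgs])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = mean[None, :] + rng.standard_normal((n, len(cpgs))) * sd[None, :]
    if clamp:
        X = np.clip(X, 0.0, 1.0)
    lp = clock.intercept + X @ coef
    return AgeDistribution(_age_transform(lp, clock.adult_age))


def age_acceleration(
    epi_ages: Sequence[float], chrono_ages: Sequence[float]
) -> np.ndarray:
    """Age acceleration: residuals of regressing epigenetic on chronological age.

    Ordinary least squares with intercept; residuals sum to zero.  Positive
    values mean biologically "older" than chronological age predicts.
    """
    epi = np.asarray(epi_ages, dtype=float).ravel()
    chrono = np.asarray(chrono_ages, dtype=float).ravel()
    if epi.size != chrono.size:
        raise ValueError("epigenetic and chronological age vectors must match")
    if epi.size < 3:
        raise ValueError("at least 3 pairs are required")
    if np.ptp(chrono) == 0:
        raise ValueError("constant chronological age: regression design is degenerate")
    slope, intercept = np.polyfit(chrono, epi, deg=1)
    return epi - (slope * chrono + intercept)


def load_clock(
    path, name: str | None = None, adult_age: float = 20.0
) -> ClockDefinition:
    """Read a clock coefficient table (CSV: ``cpg_id,coefficient``).

    The intercept is the row with the reserved id ``(Intercept)`` and is
    required; duplicate CpG ids are a format error.
    """
    table = pd.read_csv(path, comment="#")
    required = {"cpg_id", "coefficient"}
    if not required.issubset(table.columns):
        raise ValueError(f"clock file must have columns {sorted(required)}")
    dup = table["cpg_id"][table["cpg_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate CpG ids in clock file: {sorted(set(dup))[:5]}")
    mask = table["cpg_id"] == INTERCEPT_ID
    if not mask.any():
        raise ValueError(f"clock file misses the required {INTERCEPT_ID!r} row")
    intercept = float(table.loc[mask, "coefficient"].iloc[0])
    rest = table[~mask]
    coefficients = dict(zip(rest["cpg_id"].astype(str), rest["coefficient"].astype(float)))
    clock_name = name or str(getattr(path, "stem", None) or path)
    logger.info("loaded clock %s with %d CpG coefficients", clock_name, len(coefficients))
    return ClockDefinition(clock_name, intercept, coefficients, adult_age)


def write_clock(clock: ClockDefinition, path) -> None:
    """Write a clock in the loader's CSV format."""
    rows = [{"cpg_id": INTERCEPT_ID, "coefficient": clock.intercept}]
    rows += [{"cpg_id": c, "coefficient": v} for c, v in clock.coefficients.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
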