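"""Forecast evaluation: RMSE, credible-interval coverage, and baselines.

Metrics are computed per individual-CpG series and then aggregated as mean
(SD) across series, matching the convention of reporting cohort tables of
per-series errors.  The 95% interval is the Gaussian predictive interval
``mean +/- 1.96 sd``; the CI coverage (CIC95) of a well-calibrated
forecaster should sit near the theoretical 95%.

Four reference predictors are provided for comparison with the GP
forecasts: the individual's historical mean, the leave-one-out CpG mean of
other individuals' final values, the last observed (48-month) value carried
forward, and a mixed linear model with random intercepts per individual and
per CpG (no learning between CpGs and individuals beyond additive shifts).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .forecasting import ForecastResult, batch_forecast
from .model import MethylationSeriesSet, MultiMeanGP

__all__ = [
    "rmse",
    "cic95",
    "correlate",
    "baseline_individual_mean",
    "baseline_cpg_mean",
    "baseline_last_value",
    "baseline_mixed_linear",
    "MixedLinearResult",
    "EvaluationReport",
    "evaluate_holdout",
    "holdout_report",
]


# ---------------------------------------------------------------------------
# metrics


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared error between two equal-length vectors."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size == 0 or obs.size != pred.size:
        raise ValueError(f"length mismatch or empty input: {obs.size} vs {pred.size}")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def cic95(
    observed: Sequence[float],
    pred_mean: Sequence[float],
    pred_sd: Sequence[float],
) -> float:
    """Percentage of observations inside the 95% Gaussian predictive interval."""
    obs = np.asarray(observed, dtype=float).ravel()
    mean = np.asarray(pred_mean, dtype=float).ravel()
    sd = np.asarray(pred_sd, dtype=float).ravel()
    if not (obs.size == mean.size == sd.size) or obs.size == 0:
        raise ValueError("observed, pred_mean and pred_sd must have equal non-zero length")
    if np.any(sd < 0):
        raise ValueError("pred_sd must be non-negative")
    inside = np.abs(obs - mean) <= 1.96 * sd
    return float(100.0 * np.mean(inside))


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> dict:
    """Generic association helper: correlation of two paired variables.

    Intended for downstream association tests (e.g. age acceleration
    against a clinical measure).  Pairs with a missing value are dropped.
    Returns ``{"r", "p_value", "n", "method"}``.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r} (use 'pearson' or 'spearman')")
    return {"r": float(r), "p_value": float(p), "n": int(x.size), "method": method}


# ---------------------------------------------------------------------------
# baselines


def baseline_individual_mean(train_series: Sequence[tuple[float, float]]) -> float:
    """Mean of the individual's observed betas for one CpG."""
    betas = [b for _, b in train_series]
    if not betas:
        raise ValueError("empty history")
    return float(np.mean(betas))


def baseline_cpg_mean(other_individuals_final: Sequence[float]) -> float:
    """Mean final-visit beta across the other (reference) individuals."""
    vals = np.asarray(other_individuals_final, dtype=float)
    if vals.size == 0:
        raise ValueError("no reference individuals")
    return float(np.mean(vals))


def baseline_last_value(train_series: Sequence[tuple[float, float]]) -> float:
    """Beta at the latest observed time, carried forward."""
    if not train_series:
        raise ValueError("empty history")
    t, b = max(train_series, key=lambda p: p[0])
    return float(b)


@dataclasses.dataclass
class MixedLinearResult:
    """Mixed-model predictions plus the fitted components."""

    predictions: np.ndarray
    intercept: float
    slope: float
    vc_individual: float
    vc_cpg: float
    individual_effects: dict
    cpg_effects: dict
    fallback_ols: bool


def baseline_mixed_linear(
    train: MethylationSeriesSet,
    targets: Sequence[tuple[str, str, float]],
) -> MixedLinearResult:
    """Random-intercept mixed model ``y = b0 + b1 t + u_i + v_j + eps``.

    Fitted by (restricted) maximum likelihood with crossed random
    intercepts per individual and per CpG; predictions use the fixed line
    plus estimated intercepts (zero for unseen entities).  Falls back to
    pooled ordinary regression with a warning when the mixed fit fails.
    """
    frame = train.frame
    if train.times.size < 2:
        raise ValueError("mixed model needs at least 2 distinct timepoints")
    ind_eff: dict = {}
    cpg_eff: dict = {}
    vc_ind = vc_cpg = 0.0
    fallback = False
    try:
        df = frame.assign(_g=1)
        md = smf.mixedlm(
            "beta ~ age_years",
            df,
            groups=df["_g"],
            vc_formula={
                "individual": "0 + C(individual_id)",
                "cpg": "0 + C(cpg_id)",
            },
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=True, method="lbfgs", maxiter=200)
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite mixed-model parameters")
        intercept = float(res.params["Intercept"])
        slope = float(res.params["age_years"])
        vc_names = list(md.exog_vc.names)
        vc_ind = float(res.vcomp[vc_names.index("individual")])
        vc_cpg = float(res.vcomp[vc_names.index("cpg")])
        re = res.random_effects[1]
        for key, val in re.items():
            if key.startswith("individual["):
                ind_eff[key[len("individual[C(individual_id)[") : -2]] = float(val)
            elif key.startswith("cpg["):
                cpg_eff[key[len("cpg[C(cpg_id)[") : -2]] = float(val)
    except Exception as exc:  # noqa: BLE001 - optimizer failures vary widely
        warnings.warn(
            f"mixed linear fit failed ({exc}); falling back to pooled OLS",
            RuntimeWarning,
        )
        fallback = True
        slope, intercept = np.polyfit(
            frame["age_years"].to_numpy(), frame["beta"].to_numpy(), deg=1
        )
    preds = np.array(
        [
            intercept
            + slope * t
            + ind_eff.get(ind, 0.0)
            + cpg_eff.get(cpg, 0.0)
            for ind, cpg, t in targets
        ]
    )
    return MixedLinearResult(
        preds, float(intercept), float(slope), vc_ind, vc_cpg, ind_eff, cpg_eff, fallback
    )


# ---------------------------------------------------------------------------
# report


@dataclasses.dataclass
class EvaluationReport:
    """Per-method aggregate metrics and the per-series error table."""

    table: pd.DataFrame
    per_series: pd.DataFrame

    @property
    def methods(self) -> list[str]:
        return list(self.table["method"])

    def rmse_mean(self, method: str) -> float:
        return float(self.table.set_index("method").loc[method, "rmse_mean"])


def evaluate_holdout(
    model_predictions: Sequence[ForecastResult],
    baselines: Mapping[str, Mapping[tuple[str, str, float], float]],
    observed_final: MethylationSeriesSet,
) -> EvaluationReport:
    """Score probabilistic forecasts and point baselines on held-out data.

    ``model_predictions`` carry Gaussian forecasts; ``baselines`` maps
    method name to a dict ``(individual, cpg, time) -> predicted beta``.
    All methods must cover every held-out observation.  RMSE is computed
    per individual-CpG series then averaged (mean and SD across series);
    CIC95 is reported for the probabilistic method only.
    """
    obs = observed_final.frame
    pred_lookup: dict[tuple[str, str, float], tuple[float, float]] = {}
    for fr in model_predictions:
        sd = fr.belief.sd()
        for k, t in enumerate(fr.target_times):
            pred_lookup[(fr.individual_id, fr.cpg_id, float(t))] = (
                float(fr.belief.mean[k]),
                float(sd[k]),
            )

    rows = []
    for (ind, cpg), grp in obs.groupby(["individual_id", "cpg_id"]):
        times = grp["age_years"].to_numpy()
        y = grp["beta"].to_numpy()
        keys = [(ind, cpg, float(t)) for t in times]
        missing = [k for k in keys if k not in pred_lookup]
        if missing:
            raise KeyError(f"model predictions missing for {missing[:3]}")
        mean = np.array([pred_lookup[k][0] for k in keys])
        sd = np.array([pred_lookup[k][1] for k in keys])
        row = {
            "individual_id": ind,
            "cpg_id": cpg,
            "n_points": len(y),
            "rmse_multimean_gp": rmse(y, mean),
            "cic95_multimean_gp": cic95(y, mean, sd),
        }
        for name, lookup in baselines.items():
            miss = [k for k in keys if k not in lookup]
            if miss:
                raise KeyError(f"baseline {name!r} missing predictions for {miss[:3]}")
            row[f"rmse_{name}"] = rmse(y, np.array([lookup[k] for k in keys]))
        rows.append(row)
    per_series = pd.DataFrame(rows)

    summary = [
        {
            "method": "multimean_gp",
            "rmse_mean": float(per_series["rmse_multimean_gp"].mean()),
            "rmse_sd": float(per_series["rmse_multimean_gp"].std(ddof=1)),
            "cic95_mean": float(per_series["cic95_multimean_gp"].mean()),
            "cic95_sd": float(per_series["cic95_multimean_gp"].std(ddof=1)),
        }
    ]
    for name in baselines:
        summary.append(
            {
                "method": name,
                "rmse_mean": float(per_series[f"rmse_{name}"].mean()),
                "rmse_sd": float(per_series[f"rmse_{name}"].std(ddof=1)),
                "cic95_mean": float("nan"),
                "cic95_sd": float("nan"),
            }
        )
    return EvaluationReport(pd.DataFrame(summary), per_series)


def holdout_report(
    model: MultiMeanGP,
    test_observed: MethylationSeriesSet,
    test_holdout: MethylationSeriesSet,
    mixed_train: MethylationSeriesSet | None = None,
) -> EvaluationReport:
    """End-to-end comparison of GP forecasts against the four baselines.

    Forecasts every held-out point from the individual's observed history,
    then scores against: individual mean, leave-one-out CpG mean of other
    individuals' final values, last observed value, and the mixed linear
    model (fitted on ``mixed_train`` plus the observed test records so that
    test individuals receive estimated intercepts).
    """
    holdout = test_holdout.frame
    target_times = np.unique(holdout["age_years"].to_numpy())
    cpgs = test_holdout.cpgs

    results = batch_forecast(model, test_observed, target_times, cpgs)

    obs_series: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for (ind, cpg), grp in test_observed.frame.groupby(["individual_id", "cpg_id"]):
        obs_series[(ind, cpg)] = list(zip(grp["age_years"], grp["beta"]))

    final_by_cpg: dict[str, dict[str, float]] = {}
    for (ind, cpg), grp in holdout.groupby(["individual_id", "cpg_id"]):
        last = grp.loc[grp["age_years"].idxmax()]
        final_by_cpg.setdefault(cpg, {})[ind] = float(last["beta"])

    keys = [
        (str(r.individual_id), str(r.cpg_id), float(r.age_years))
        for r in holdout.itertuples()
    ]
    ind_mean = {}
    last_val = {}
    cpg_mean = {}
    for key in keys:
        ind, cpg, _ = key
        series = obs_series.get((ind, cpg), [])
        ind_mean[key] = baseline_individual_mean(series)
        last_val[key] = baseline_last_value(series)
        others = [v for o, v in final_by_cpg.get(cpg, {}).items() if o != ind]
        cpg_mean[key] = baseline_cpg_mean(others)

    mixed_frames = [test_observed.frame]
    if mixed_train is not None:
        mixed_frames.insert(0, mixed_train.frame)
    mixed_data = MethylationSeriesSet(
        pd.concat(mixed_frames, ignore_index=True), validate=False
    )
    mixed = baseline_mixed_linear(mixed_data, keys)
    mixed_lookup = dict(zip(keys, mixed.predictions))

    baselines = {
        "individual_mean": ind_mean,
        "cpg_mean": cpg_mean,
        "last_value": last_val,
        "mixed_linear": mixed_lookup,
    }
    return evaluate_holdout(results, baselines, test_holdout)
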