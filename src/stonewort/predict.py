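"""Posterior prediction surfaces, effect summaries and lake triage.

Per-point occupancy probabilities are summarized as posterior medians with
central 95% credible intervals.  Lakes are triaged into four qualitative
classes from the posterior of the lake-mean occupancy probability (drawn
coherently: average across points within each posterior draw, then
summarize) crossed with the width of its 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from stonewort.covariates import OccupancyDesign, observed_occupancy_rates
from stonewort.errors import ConfigurationError, SchemaError
from stonewort.model import PosteriorSamples


@dataclass
class PredictionSurface:
    """Per-point posterior occupancy summaries for one target year.

    ``draws`` has shape (n_draws, n_points) and is kept so lake-level
    summaries can be computed draw-wise.
    """

    table: pd.DataFrame
    draws: np.ndarray
    year: int

    def __post_init__(self) -> None:
        t = self.table
        ok = (
            (t["lower"] >= 0)
            & (t["lower"] <= t["median"])
            & (t["median"] <= t["upper"])
            & (t["upper"] <= 1)
        )
        if not ok.all():
            raise SchemaError("prediction quantiles are not ordered within [0, 1]")

    @property
    def lake_ids(self) -> np.ndarray:
        return self.table["lake_id"].to_numpy()


def predict_surface(
    samples: PosteriorSamples,
    design: OccupancyDesign,
    year: int,
    marginal_lakes: bool = False,
) -> PredictionSurface:
    """Posterior occupancy surface for every design point at ``year``.

    Per point and posterior draw: inverse-logit(x'beta + w + gamma), with
    the time covariate standardized using the training scaling.  Lakes
    absent from the fit raise unless ``marginal_lakes``, in which case
    gamma is drawn from N(0, sigma2_lake).
    """
    n = design.n_points
    X_pred = np.stack([design.occupancy_row(i, year) for i in range(n)])
    beta = samples.beta.reshape(-1, samples.beta.shape[-1])
    D = beta.shape[0]
    eta = beta @ X_pred.T
    if samples.spec.include_spatial:
        eta += samples.w.reshape(D, -1)
    if samples.spec.include_lakes:
        lake_pos = {lid: k for k, lid in enumerate(samples.lake_ids)}
        gamma = samples.gamma.reshape(D, -1)
        s2l = samples.sigma2_lake.reshape(-1)
        rng = np.random.default_rng(samples.seed + 0x5EED)
        for i, lid in enumerate(design.point_table["lake_id"]):
            if lid in lake_pos:
                eta[:, i] += gamma[:, lake_pos[lid]]
            elif marginal_lakes:
                eta[:, i] += rng.standard_normal(D) * np.sqrt(s2l)
            else:
                raise ConfigurationError(
                    f"no lake intercept draws for {lid!r}; "
                    "set marginal_lakes=True to integrate over new lakes"
                )
    psi = expit(eta)
    lo, med, hi = np.percentile(psi, [2.5, 50.0, 97.5], axis=0)
    ever = design.py.loc[design.det_any, "point_id"].unique()
    table = pd.DataFrame(
        {
            "point_id": design.point_table["point_id"].to_numpy(),
            "lake_id": design.point_table["lake_id"].to_numpy(),
            "x": design.point_coords[:, 0],
            "y": design.point_coords[:, 1],
            "median": med,
            "lower": lo,
            "upper": hi,
            "width": hi - lo,
            "ever_detected": design.point_table["point_id"].isin(ever).to_numpy(),
        }
    )
    return PredictionSurface(table=table, draws=psi, year=int(year))


def significance(
    samples: PosteriorSamples, parameter: str
) -> tuple[bool, tuple[float, float]]:
    """CI-based significance call for a named coefficient.

    The 95% CI is the (2.5, 97.5) percentile interval of the draws; the
    parameter is significant iff 0 falls outside it.
    """
    draws = samples.coef_draws(parameter)
    if draws.size < 100:
        raise SchemaError("need >= 100 retained draws for a stable 95% CI")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return bool(not (lo <= 0.0 <= hi)), (float(lo), float(hi))


def detection_at_mean(intercept) -> float:
    """Average detection probability (percent) at scaled-mean covariates.

    With all detection covariates at their scaled means of 0, detection
    probability is the inverse-logit of the intercept.  Accepts posterior
    samples (uses the posterior mean of the detection intercept), an array
    of draws, or a point estimate.
    """
    if isinstance(intercept, PosteriorSamples):
        value = float(np.mean(intercept.stacked("alpha", 0)))
    else:
        value = float(np.mean(intercept))
    return float(expit(value) * 100.0)


def max_prob_change_per_sd(coefficient: float) -> float:
    """Maximum probability change (percent) per 1 SD covariate change.

    The logistic derivative is at most 1/4, so a logit-scale effect b
    moves the probability by at most |b|/4 per standard deviation; the
    result is reported in percent to one decimal.
    """
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    return round(abs(float(coefficient)) * 0.25 * 100.0, 1)


@dataclass(frozen=True)
class ClassThresholds:
    """Decision rule for the four-class lake triage.

    Mean-occupancy boundaries (0.010, 0.160, 0.349) follow the observed
    class envelopes; width tiers split 'low' / 'modest' / 'large'
    uncertainty.  The rule is total over the (mean, width) unit square:

    - class 4: mean < psi_low  and width <= width_low   (low, certain)
    - class 1: mean > psi_high and width >  width_high  (high, uncertain)
    - class 3: mean < psi_mid                           (low-to-moderate)
    - class 2: otherwise                                (moderate, modest CI)

    This is a triage heuristic layered on the model output, not a model
    quantity itself.
    """

    psi_low: float = 0.010
    psi_mid: float = 0.160
    psi_high: float = 0.349
    width_low: float = 0.05
    width_high: float = 0.12

    def classify(self, mean_psi: float, width: float) -> int:
        if mean_psi < self.psi_low and width <= self.width_low:
            return 4
        if mean_psi > self.psi_high and width > self.width_high:
            return 1
        if mean_psi < self.psi_mid:
            return 3
        return 2


def lake_mean_summaries(surface: PredictionSurface) -> pd.DataFrame:
    """Posterior of per-lake mean occupancy (draw-wise across points)."""
    rows = []
    for lake_id in np.unique(surface.lake_ids):
        cols = np.flatnonzero(surface.lake_ids == lake_id)
        if cols.size == 0:
            raise SchemaError(f"lake {lake_id!r} has no predicted points")
        lake_draws = surface.draws[:, cols].mean(axis=1)
        lo, hi = np.percentile(lake_draws, [2.5, 97.5])
        rows.append(
            {
                "lake_id": lake_id,
                "mean_psi": float(lake_draws.mean()),
                "lower": float(lo),
                "upper": float(hi),
                "width": float(hi - lo),
                "n_points": int(cols.size),
            }
        )
    return pd.DataFrame(rows)


def classify_lakes(
    surface: PredictionSurface,
    thresholds: ClassThresholds | None = None,
) -> pd.DataFrame:
    """Assign each lake one of four triage classes.

    Output columns: lake_id, mean_psi, lower, upper, width, n_points,
    lake_class.  Invariant to point ordering and duplication of a lake's
    point set (the lake mean is unchanged by either).
    """
    thresholds = thresholds or ClassThresholds()
    out = lake_mean_summaries(surface)
    if out.empty:
        raise SchemaError("no lakes to classify")
    out["lake_class"] = [
        thresholds.classify(m, w) for m, w in zip(out["mean_psi"], out["width"])
    ]
    return out


def concordance(
    surface_or_means: PredictionSurface | pd.DataFrame | pd.Series,
    observed: pd.Series,
) -> float:
    """Spearman rank correlation of predicted vs observed lake occupancy.

    ``observed`` is the per-lake proportion of points with >= 1 detection
    (see :func:`stonewort.covariates.observed_occupancy_rates`).
    """
    if isinstance(surface_or_means, PredictionSurface):
        means = lake_mean_summaries(surface_or_means).set_index("lake_id")["mean_psi"]
    elif isinstance(surface_or_means, pd.DataFrame):
        means = surface_or_means.set_index("lake_id")["mean_psi"]
    else:
        means = surface_or_means
    joined = pd.concat([means.rename("pred"), observed.rename("obs")], axis=1).dropna()
    if len(joined) < 3:
        raise SchemaError("concordance needs >= 3 lakes")
    if joined["pred"].nunique() == 1 or joined["obs"].nunique() == 1:
        import warnings

        warnings.warn("constant vector; rank correlation undefined", stacklevel=2)
        return float("nan")
    rho, _ = spearmanr(joined["pred"], joined["obs"])
    return float(rho)


def predicted_vs_observed(
    surface: PredictionSurface, design: OccupancyDesign
) -> tuple[float, pd.DataFrame]:
    """Convenience: concordance plus the per-lake comparison table."""
    obs = observed_occupancy_rates(design)
    means = lake_mean_summaries(surface)
    table = means.merge(
        obs.rename("observed_rate"), left_on="lake_id", right_index=True
    )
    return concordance(means, obs), table
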