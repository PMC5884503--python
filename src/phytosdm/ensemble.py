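"""5-fold cross-validation, correlation-derived ensemble weights, ensemble
prediction, and the evaluation metric suite (rho, R2, RMSE, MAE, ME).

Weight rule: each member's weight is proportional to its pooled
cross-validated Pearson correlation between predicted and observed values,
clamped at zero and normalized to sum to one.  Metrics are computed on the
log (fitting) scale from out-of-fold predictions pooled across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .data_model import CovariateStack, GridMap, SiteTable, back_transform
from .errors import ConfigurationError, DegeneracyError, GeometryError
from . import learners

LearnerSpec = Callable[[SiteTable, int], learners.ModelFit]

DEFAULT_K = 5


def default_learner_specs(
    gam_variables: list[str] | None = None,
    rf_settings: Mapping | None = None,
    lasso_settings: Mapping | None = None,
    gam_settings: Mapping | None = None,
) -> dict[str, LearnerSpec]:
    """The paper-configured trio.  ``gam_variables=None`` uses all covariates."""
    rf_settings = dict(rf_settings or {})
    lasso_settings = dict(lasso_settings or {})
    gam_settings = dict(gam_settings or {})

    def rf(sites: SiteTable, seed: int) -> learners.ModelFit:
        return learners.fit_random_forest(sites, seed=seed, **rf_settings)

    def lasso(sites: SiteTable, seed: int) -> learners.ModelFit:
        return learners.fit_lasso(sites, seed=seed, **lasso_settings)

    def gam(sites: SiteTable, seed: int) -> learners.ModelFit:
        variables = gam_variables if gam_variables is not None else sites.covariate_names
        return learners.fit_gam(sites, variables, **gam_settings)

    return {"random_forest": rf, "lasso": lasso, "gam": gam}


# ---------------------------------------------------------------------------
# metrics


def metrics(observed: np.ndarray, predicted: np.ndarray) -> dict:
    """rho, R2, RMSE, MAE, ME (= mean(predicted - observed)), median error.

    Degenerate cases are flagged rather than propagated as NaN: constant
    predictions give rho = 0 with ``rho_degenerate``; constant observations
    give R2 = NaN with ``r2_degenerate``.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ConfigurationError("observed/predicted length mismatch")
    n = observed.size
    if n < 2:
        raise ConfigurationError("need at least 2 observations")
    err = predicted - observed
    out = {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "me": float(np.mean(err)),
        "median_error": float(np.median(err)),
        "n": int(n),
        "rho_degenerate": False,
        "r2_degenerate": False,
    }
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        out["r2"] = float("nan")
        out["r2_degenerate"] = True
    else:
        out["r2"] = float(1.0 - np.sum(err**2) / ss_tot)
    if np.std(predicted) == 0 or np.std(observed) == 0:
        out["rho"] = 0.0
        out["rho_degenerate"] = True
    else:
        out["rho"] = float(stats.pearsonr(observed, predicted)[0])
    return out


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    """Pooled out-of-fold metrics per learner plus the shared fold map."""

    learner_metrics: dict[str, dict]
    fold_assignment: dict[str, int]  # site_id -> fold in 1..k
    k: int
    seed: int
    oof_predictions: dict[str, np.ndarray] = field(default_factory=dict)
    observed: np.ndarray | None = None

    def rho(self, name: str) -> float:
        return self.learner_metrics[name]["rho"]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "learner_metrics": {
                name: {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in m.items()}
                for name, m in self.learner_metrics.items()
            },
            "fold_assignment": dict(self.fold_assignment),
        }


def make_folds(site_ids: np.ndarray, k: int, seed: int) -> dict[str, int]:
    """Shared random partition into k folds with sizes differing by <= 1."""
    n = len(site_ids)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds n={n} sites")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))
    order = rng.permutation(n)
    assignment: dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        for idx in chunk:
            assignment[str(site_ids[idx])] = fold
    return assignment


def kfold_cv(
    sites: SiteTable,
    specs: Mapping[str, LearnerSpec],
    k: int = DEFAULT_K,
    seed: int = 0,
) -> CVReport:
    """k-fold CV with one shared partition for every learner; metrics on the
    log scale from pooled out-of-fold predictions."""
    if not specs:
        raise ConfigurationError("no learner specs given")
    assignment = make_folds(sites.site_ids, k, seed)
    folds = np.array([assignment[str(s)] for s in sites.site_ids])
    observed = sites.log_response
    oof = {name: np.full(sites.n, np.nan) for name in specs}
    for fold in range(1, k + 1):
        test = folds == fold
        train_sites = sites.subset(~test)
        test_sites = sites.subset(test)
        for name, spec in specs.items():
            fit = spec(train_sites, int(seed))
            oof[name][test] = learners.predict_sites(fit, test_sites)
    learner_metrics = {name: metrics(observed, preds) for name, preds in oof.items()}
    return CVReport(
        learner_metrics=learner_metrics,
        fold_assignment=assignment,
        k=k,
        seed=int(seed),
        oof_predictions=oof,
        observed=observed,
    )


# ---------------------------------------------------------------------------
# weights and the ensemble


def compute_weights(cv: CVReport) -> dict[str, float]:
    """w_m = max(rho_m, 0) / sum_j max(rho_j, 0); equal weights (with a
    warning) when no learner achieves positive correlation."""
    if not cv.learner_metrics:
        raise ConfigurationError("empty CV report")
    rhos = {name: m["rho"] for name, m in cv.learner_metrics.items()}
    if not any(np.isfinite(r) for r in rhos.values()):
        raise ConfigurationError("no learner has a finite CV correlation")
    clamped = {name: max(float(r), 0.0) if np.isfinite(r) else 0.0 for name, r in rhos.items()}
    total = sum(clamped.values())
    if total == 0:
        warnings.warn("all CV correlations <= 0; falling back to equal weights")
        return {name: 1.0 / len(clamped) for name in clamped}
    return {name: v / total for name, v in clamped.items()}


@dataclass
class EnsembleModel:
    """Member fits (refit on all data) + normalized nonnegative weights."""

    fits: dict[str, learners.ModelFit]
    weights: dict[str, float]
    cv_report: CVReport | None = None

    def __post_init__(self):
        if set(self.fits) != set(self.weights):
            raise ConfigurationError("fits and weights must cover the same learners")
        total = sum(self.weights.values())
        if any(w < 0 for w in self.weights.values()) or abs(total - 1.0) > 1e-12:
            raise ConfigurationError("weights must be nonnegative and sum to 1")


def fit_ensemble(
    sites: SiteTable,
    specs: Mapping[str, LearnerSpec],
    k: int = DEFAULT_K,
    seed: int = 0,
) -> EnsembleModel:
    """CV -> correlation weights -> members refit on all data."""
    cv = kfold_cv(sites, specs, k=k, seed=seed)
    weights = compute_weights(cv)
    fits = {name: spec(sites, int(seed)) for name, spec in specs.items()}
    return EnsembleModel(fits=fits, weights=weights, cv_report=cv)


def ensemble_predict_sites(model: EnsembleModel, sites: SiteTable) -> np.ndarray:
    """Weighted per-site log-scale prediction."""
    total = np.zeros(sites.n)
    for name, fit in model.fits.items():
        total += model.weights[name] * learners.predict_sites(fit, sites)
    return total


def ensemble_predict(
    model: EnsembleModel,
    stack: CovariateStack,
    back_transform_flag: bool = False,
) -> GridMap:
    """Weighted sum of member log-scale maps; optionally exponentiated per
    cell (naive back-transform).  Missing cells propagate."""
    member_maps = [learners.predict_raster(fit, stack) for fit in model.fits.values()]
    geometry = member_maps[0].geometry
    for m in member_maps[1:]:
        if m.geometry != geometry:
            raise GeometryError("member prediction maps disagree on geometry")
    values = np.zeros(geometry.shape)
    mask = member_maps[0].mask.copy()
    for gmap, name in zip(member_maps, model.fits):
        values += model.weights[name] * gmap.values
        mask &= gmap.mask
    if back_transform_flag:
        values = back_transform(values)
        units = "percent"
    else:
        units = "log percent"
    values[~mask] = 0.0
    return GridMap(values, mask, geometry, name="ensemble_prediction", units=units)


def ensemble_fit_statistics(model: EnsembleModel, sites: SiteTable) -> dict:
    """Training-data (resubstitution) metrics on the log scale: R2, MAE,
    ME (predicted - observed), and median error."""
    predicted = ensemble_predict_sites(model, sites)
    m = metrics(sites.log_response, predicted)
    return {
        "r2": m["r2"],
        "mae": m["mae"],
        "me": m["me"],
        "median_error": m["median_error"],
        "n": m["n"],
    }
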