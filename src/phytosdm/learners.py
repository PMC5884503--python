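"""The three abundance learners and their variable-importance metrics.

All learners fit and predict on the natural-log response scale; the ensemble
module owns back-transformation.

* random forest: 2000 trees, 2 candidate variables per split (mtry=2),
  variance-reduction splits, minimum node size 5.
* lasso: internally standardized design, penalty chosen by internal 10-fold
  CV minimizing mean squared error over a 100-value log-scale path.
* additive model: univariate penalized cubic B-splines (k=10 basis functions
  per term, second-difference penalty) with an extra penalty on each
  smooth's null space so over-smoothed terms can shrink to ~zero influence;
  smoothing parameters selected by generalized cross-validation (GCV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV, Lasso
from sklearn.model_selection import KFold

from .data_model import CovariateStack, GridMap, SiteTable
from .errors import ConfigurationError, DomainError, GeometryError

MIN_SITES = 10

RF_DEFAULTS = dict(n_trees=2000, mtry=2, min_node_size=5)
LASSO_DEFAULTS = dict(cv_folds=10, n_lambdas=100)
GAM_DEFAULTS = dict(basis_size=10, min_distinct=10)


# ---------------------------------------------------------------------------
# fit containers


@dataclass
class ModelFit:
    """A fitted learner with its prediction contract on the log scale."""

    kind: str  # random_forest | lasso | gam
    variables: list[str]
    response_scale: str = "log"
    seed: int | None = None
    settings: dict = field(default_factory=dict)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in frame.columns]
        if missing:
            raise ConfigurationError(f"prediction input missing variables: {missing}")
        return self.predict_matrix(frame[self.variables].to_numpy(dtype=float))


@dataclass
class RandomForestFit(ModelFit):
    forest: RandomForestRegressor | None = None
    oob_r2: float | None = None

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(X)


@dataclass
class LassoFit(ModelFit):
    coef_std: np.ndarray | None = None  # coefficients on the standardized scale
    intercept: float = 0.0
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    lambda_: float | None = None
    dropped: list[str] = field(default_factory=list)  # zero-variance variables

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.x_mean) / self.x_scale
        return self.intercept + Z @ self.coef_std


@dataclass
class GamFit(ModelFit):
    terms: list[dict] = field(default_factory=list)
    coef: np.ndarray | None = None
    lambdas: np.ndarray | None = None
    gcv: float | None = None
    edf: float | None = None
    y_train: np.ndarray | None = None
    selection: str = "GCV"

    def design(self, X: np.ndarray) -> np.ndarray:
        cols = [np.ones((X.shape[0], 1))]
        for j, term in enumerate(self.terms):
            cols.append(_term_design(term, X[:, j]))
        return np.hstack(cols)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.design(X) @ self.coef


# ---------------------------------------------------------------------------
# random forest


def fit_random_forest(
    sites: SiteTable,
    seed: int,
    n_trees: int = RF_DEFAULTS["n_trees"],
    mtry: int = RF_DEFAULTS["mtry"],
    min_node_size: int = RF_DEFAULTS["min_node_size"],
    variables: list[str] | None = None,
) -> RandomForestFit:
    """Regression forest on the log response; deterministic given seed."""
    variables = list(variables) if variables is not None else sites.covariate_names
    if len(variables) < 2:
        raise ConfigurationError("random forest needs at least 2 covariates")
    if sites.n < MIN_SITES:
        raise ConfigurationError(f"need >= {MIN_SITES} sites, got {sites.n}")
    X = sites.covariate_matrix(variables)
    y = sites.log_response
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=min(mtry, len(variables)),
        min_samples_leaf=min_node_size,
        random_state=int(seed),
        oob_score=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # oob warning for tiny n
        forest.fit(X, y)
    oob = float(forest.oob_score_) if hasattr(forest, "oob_score_") else None
    return RandomForestFit(
        kind="random_forest",
        variables=variables,
        seed=int(seed),
        settings=dict(n_trees=n_trees, mtry=mtry, min_node_size=min_node_size),
        forest=forest,
        oob_r2=oob,
    )


# ---------------------------------------------------------------------------
# lasso


def fit_lasso(
    sites: SiteTable,
    seed: int,
    lambda_: float | None = None,
    cv_folds: int = LASSO_DEFAULTS["cv_folds"],
    n_lambdas: int = LASSO_DEFAULTS["n_lambdas"],
    variables: list[str] | None = None,
) -> LassoFit:
    """Lasso on an internally standardized design.

    With ``lambda_=None`` the penalty is chosen by k-fold CV minimizing mean
    squared error (the CV-optimal lambda).  ``lambda_=0`` gives the least
    squares solution.  The penalized objective is
    ``(1/2n)||y - Z b||^2 + lambda * sum|b|`` on the standardized design Z.
    """
    if sites.n < MIN_SITES:
        raise ConfigurationError(f"need >= {MIN_SITES} sites, got {sites.n}")
    variables = list(variables) if variables is not None else sites.covariate_names
    X = sites.covariate_matrix(variables)
    y = sites.log_response

    scale = X.std(axis=0)
    zero_var = scale == 0
    dropped = [v for v, z in zip(variables, zero_var) if z]
    if dropped:
        warnings.warn(f"dropping zero-variance covariates for lasso: {dropped}")
        keep = ~zero_var
        variables = [v for v, k in zip(variables, keep) if k]
        X, scale = X[:, keep], scale[keep]
    mean = X.mean(axis=0)
    Z = (X - mean) / scale

    if lambda_ is None:
        model = LassoCV(
            alphas=n_lambdas,
            cv=KFold(n_splits=min(cv_folds, sites.n), shuffle=True, random_state=int(seed)),
            max_iter=50000,
        )
        model.fit(Z, y)
        coef, intercept, chosen = model.coef_, float(model.intercept_), float(model.alpha_)
    elif lambda_ == 0:
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), Z]), y, rcond=None)
        coef, intercept, chosen = beta[1:], float(beta[0]), 0.0
    else:
        model = Lasso(alpha=float(lambda_), max_iter=50000)
        model.fit(Z, y)
        coef, intercept, chosen = model.coef_, float(model.intercept_), float(lambda_)

    return LassoFit(
        kind="lasso",
        variables=variables,
        seed=int(seed),
        settings=dict(cv_folds=cv_folds, n_lambdas=n_lambdas, lambda_=chosen),
        coef_std=np.asarray(coef, dtype=float),
        intercept=intercept,
        x_mean=mean,
        x_scale=scale,
        lambda_=chosen,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# additive model (penalized B-splines with null-space shrinkage)


def _spline_knots(x: np.ndarray, n_basis: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo if hi > lo else 1.0
    lo -= 1e-8 * span
    hi += 1e-8 * span
    n_interior = n_basis - 4
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior > 0 else []
    interior = np.clip(interior, lo, hi)
    return np.concatenate([[lo] * 4, np.sort(interior), [hi] * 4])


def _term_design(term: dict, x: np.ndarray) -> np.ndarray:
    """Evaluate a term's (centered) basis at x; x is clipped to the
    training range so raster prediction never extrapolates the splines."""
    if term["type"] == "linear":
        return (np.clip(x, term["lo"], term["hi"]) - term["center"])[:, None]
    knots = term["knots"]
    xc = np.clip(x, knots[0], knots[-1])
    B = BSpline.design_matrix(xc, knots, 3).toarray()
    return B - term["center"]


def _build_term(x: np.ndarray, name: str, n_basis: int, min_distinct: int) -> dict:
    distinct = np.unique(x).size
    if distinct < min_distinct:
        term = {
            "type": "linear",
            "name": name,
            "lo": float(x.min()),
            "hi": float(x.max()),
            "center": float(x.mean()),
        }
        # a 1x1 "null-space" penalty: the linear term itself is shrinkable
        term["S"] = np.zeros((1, 1))
        term["N"] = np.eye(1)
        return term
    knots = _spline_knots(x, n_basis)
    B = BSpline.design_matrix(x, knots, 3).toarray()
    center = B.mean(axis=0)
    k = B.shape[1]
    D2 = np.diff(np.eye(k), n=2, axis=0)
    S = D2.T @ D2
    eigval, eigvec = np.linalg.eigh(S)
    S = S / eigval.max()
    null = eigvec[:, eigval < 1e-10 * eigval.max()]
    N = null @ null.T  # projection onto the penalty null space (constant+linear)
    return {"type": "spline", "name": name, "knots": knots, "center": center, "S": S, "N": N}


_LAMBDA_GRID = np.logspace(-4, 7, 12)


def _gam_solve(
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    blocks: list[tuple[int, int]],
    terms: list[dict],
    lambdas: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Solve the penalized normal equations; return (coef, edf, gcv)."""
    P = np.zeros_like(XtX)
    for (a, b), term, lam in zip(blocks, terms, lambdas):
        P[a:b, a:b] = lam * (term["S"] + term["N"])
    A = XtX + P + 1e-10 * np.eye(XtX.shape[0])
    c, low = cho_factor(A)
    coef = cho_solve((c, low), Xty)
    edf = float(np.trace(cho_solve((c, low), XtX)))
    rss = max(yty - 2 * coef @ Xty + coef @ XtX @ coef, 0.0)
    denom = max(n - edf, 1e-8)
    gcv = n * rss / denom**2
    return coef, edf, gcv


def fit_gam(
    sites: SiteTable,
    variables: list[str],
    basis_size: int = GAM_DEFAULTS["basis_size"],
    min_distinct: int = GAM_DEFAULTS["min_distinct"],
    n_sweeps: int = 3,
) -> GamFit:
    """Additive model of univariate penalized smooths on the log response.

    Each smooth carries a second penalty on its null space, so GCV can
    shrink a term to essentially zero influence (term removal).  Smoothing
    parameters are selected by coordinate-wise grid search minimizing GCV.
    """
    if not variables:
        raise ConfigurationError("GAM variable subset must be non-empty")
    unknown = [v for v in variables if v not in sites.frame.columns]
    if unknown:
        raise ConfigurationError(f"GAM subset names unknown variables: {unknown}")
    variables = list(variables)
    X = sites.covariate_matrix(variables)
    y = sites.log_response
    n = len(y)

    zero_var = X.std(axis=0) == 0
    if zero_var.any():
        dropped = [v for v, z in zip(variables, zero_var) if z]
        warnings.warn(f"dropping zero-variance covariates for GAM: {dropped}")
        variables = [v for v, z in zip(variables, zero_var) if not z]
        X = X[:, ~zero_var]
        if not variables:
            raise ConfigurationError("all GAM variables have zero variance")

    terms = [
        _build_term(X[:, j], name, basis_size, min_distinct) for j, name in enumerate(variables)
    ]
    cols = [np.ones((n, 1))]
    blocks: list[tuple[int, int]] = []
    offset = 1
    for j, term in enumerate(terms):
        Bj = _term_design(term, X[:, j])
        cols.append(Bj)
        blocks.append((offset, offset + Bj.shape[1]))
        offset += Bj.shape[1]
    design = np.hstack(cols)
    XtX = design.T @ design
    Xty = design.T @ y
    yty = float(y @ y)

    lambdas = np.ones(len(terms))
    coef, edf, best_gcv = _gam_solve(XtX, Xty, yty, n, blocks, terms, lambdas)
    for _ in range(n_sweeps):
        improved = False
        for j in range(len(terms)):
            for lam in _LAMBDA_GRID:
                if lam == lambdas[j]:
                    continue
                trial = lambdas.copy()
                trial[j] = lam
                c_, e_, g_ = _gam_solve(XtX, Xty, yty, n, blocks, terms, trial)
                if g_ < best_gcv - 1e-12:
                    lambdas, coef, edf, best_gcv = trial, c_, e_, g_
                    improved = True
        if not improved:
            break

    return GamFit(
        kind="gam",
        variables=variables,
        settings=dict(basis_size=basis_size, min_distinct=min_distinct, selection="GCV"),
        terms=terms,
        coef=coef,
        lambdas=lambdas,
        gcv=best_gcv,
        edf=edf,
        y_train=y,
        selection="GCV",
    )


# ---------------------------------------------------------------------------
# variable importance


@dataclass
class ImportanceTable:
    """Per-variable raw and max-scaled importance scores."""

    frame: pd.DataFrame  # columns: variable, raw, scaled, sign
    top_variable: str
    degenerate: bool = False

    def scaled(self, variable: str) -> float:
        row = self.frame.loc[self.frame["variable"] == variable]
        return float(row["scaled"].iloc[0])


def _make_table(variables: list[str], raw: np.ndarray, signs: np.ndarray | None) -> ImportanceTable:
    raw = np.asarray(raw, dtype=float)
    max_raw = raw.max() if raw.size else 0.0
    degenerate = max_raw <= 0
    scaled = raw / max_raw if not degenerate else np.zeros_like(raw)
    frame = pd.DataFrame(
        {
            "variable": variables,
            "raw": raw,
            "scaled": scaled,
            "sign": signs if signs is not None else [""] * len(variables),
        }
    )
    # top variable: highest scaled score, ties broken by name order
    order = sorted(range(len(variables)), key=lambda i: (-scaled[i], variables[i]))
    return ImportanceTable(frame=frame, top_variable=variables[order[0]], degenerate=degenerate)


def variable_importance(fit: ModelFit, sites: SiteTable | None = None) -> ImportanceTable:
    """Learner-specific importance, scaled by the maximum score.

    forest: mean split-criterion (impurity) decrease per variable.
    lasso: |standardized coefficient|, sign retained.
    gam: chi-square-style score from refitting with each smooth removed and
    comparing residual deviance.
    """
    if isinstance(fit, RandomForestFit):
        return _make_table(fit.variables, fit.forest.feature_importances_, None)
    if isinstance(fit, LassoFit):
        signs = np.where(fit.coef_std > 0, "+", np.where(fit.coef_std < 0, "-", ""))
        return _make_table(fit.variables, np.abs(fit.coef_std), signs)
    if isinstance(fit, GamFit):
        if sites is None:
            raise ConfigurationError("GAM importance needs the training sites")
        return _gam_importance(fit, sites)
    raise ConfigurationError(f"unknown fit type {type(fit)!r}")


def _gam_importance(fit: GamFit, sites: SiteTable) -> ImportanceTable:
    X = sites.covariate_matrix(fit.variables)
    y = sites.log_response
    n = len(y)
    design = fit.design(X)
    full_rss = float(np.sum((y - design @ fit.coef) ** 2))
    blocks = []
    offset = 1
    for j, term in enumerate(fit.terms):
        width = 1 if term["type"] == "linear" else len(term["center"])
        blocks.append((offset, offset + width))
        offset += width
    scores = []
    for j in range(len(fit.terms)):
        keep = np.ones(design.shape[1], dtype=bool)
        a, b = blocks[j]
        keep[a:b] = False
        Xr = design[:, keep]
        XtX = Xr.T @ Xr
        P = np.zeros_like(XtX)
        pos = 1
        for i, term in enumerate(fit.terms):
            if i == j:
                continue
            w = blocks[i][1] - blocks[i][0]
            block = fit.lambdas[i] * (term["S"] + term["N"])
            P[pos : pos + w, pos : pos + w] = block
            pos += w
        A = XtX + P + 1e-10 * np.eye(XtX.shape[0])
        coef = np.linalg.solve(A, Xr.T @ y)
        reduced_rss = float(np.sum((y - Xr @ coef) ** 2))
        scores.append(max(reduced_rss - full_rss, 0.0))
    return _make_table(fit.variables, np.asarray(scores), None)


# ---------------------------------------------------------------------------
# prediction


def predict_sites(fit: ModelFit, sites: SiteTable) -> np.ndarray:
    """Per-site predictions on the log scale."""
    return fit.predict_frame(sites.frame)


def predict_raster(fit: ModelFit, stack: CovariateStack) -> GridMap:
    """Log-scale prediction map at cell centers; missing cells stay missing."""
    missing = [v for v in fit.variables if v not in stack]
    if missing:
        raise ConfigurationError(f"covariate stack missing layers: {missing}")
    values = np.full(stack.geometry.shape, np.nan)
    if stack.n_valid > 0:
        frame = stack.table(fit.variables)
        values.ravel()[stack.mask.ravel().nonzero()[0]] = fit.predict_frame(frame)
    return GridMap(
        np.nan_to_num(values, nan=0.0),
        stack.mask.copy(),
        stack.geometry,
        name=f"{fit.kind}_prediction",
        units="log percent",
    )


# ---------------------------------------------------------------------------
# serialization


def save_fit(fit: ModelFit, path) -> None:
    joblib.dump({"format_version": 1, "fit": fit}, path)


def load_fit(path) -> ModelFit:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise DomainError(f"unsupported fit artifact version in {path}")
    return payload["fit"]
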