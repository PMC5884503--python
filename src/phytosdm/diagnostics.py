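"""Spatial residual diagnostics and environmental-novelty mapping.

Moran's I with k-nearest-neighbour row-standardized weights and a one-sided
(greater) permutation test; pairwise residual correlation between models;
PCA-based environmental distance from sampled covariate space with a
masking rule; NPP detrending of prediction maps; and average-linkage
variable clustering on correlation distance 1 - |r|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, squareform

from .data_model import CovariateStack, GridMap, SiteTable
from .errors import ConfigurationError, DegeneracyError, GeometryError
from . import learners

KNN_DEFAULT = 5
MORAN_NSIM_DEFAULT = 999
NOVELTY_DEFAULTS = dict(n_ref=3000, n_pc=3, k_near=3)
NOVELTY_THRESHOLD_DEFAULT = 3.0


# ---------------------------------------------------------------------------
# spatial weights


@dataclass
class SpatialWeights:
    """Row-standardized k-nearest-neighbour weights.

    ``neighbors[i]`` lists the k nearest sites of site i (self excluded),
    each with weight 1/k; distance ties are broken by site_id order.
    """

    site_ids: list[str]
    neighbors: list[np.ndarray]  # indices into site_ids
    weights: list[np.ndarray]
    k: int

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (idx, w) in enumerate(zip(self.neighbors, self.weights)):
            W[i, idx] = w
        return W


def knn_weights(coords: np.ndarray, k: int, site_ids: list[str] | None = None) -> SpatialWeights:
    """k nearest neighbours by Euclidean distance, weights 1/k each."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k < 1 or k >= n:
        raise ConfigurationError(f"need 1 <= k < n, got k={k}, n={n}")
    if site_ids is None:
        site_ids = [f"s{i + 1:04d}" for i in range(n)]
    # tie-break by site_id order: stable sort over (distance, site_id rank)
    id_rank = np.argsort(np.argsort(site_ids))
    dist = cdist(coords, coords)
    neighbors, weights = [], []
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (dist[i, j], id_rank[j]))
        idx = np.array(order[:k], dtype=int)
        neighbors.append(idx)
        weights.append(np.full(k, 1.0 / k))
    return SpatialWeights(site_ids=list(site_ids), neighbors=neighbors, weights=weights, k=k)


# ---------------------------------------------------------------------------
# Moran's I


def morans_i(values: np.ndarray, weights: SpatialWeights) -> float:
    """I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2, z = value - mean."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ConfigurationError("need at least 3 sites")
    if n != weights.n:
        raise ConfigurationError("values and weights disagree on n")
    if np.ptp(values) <= np.finfo(float).eps * max(1.0, np.abs(values).max()):
        raise DegeneracyError("constant values: Moran's I undefined")
    z = values - values.mean()
    denom = float(z @ z)
    W = weights.dense()
    s0 = W.sum()
    return float((n / s0) * (z @ W @ z) / denom)


def morans_mc(
    values: np.ndarray,
    weights: SpatialWeights,
    n_sim: int = MORAN_NSIM_DEFAULT,
    seed: int = 0,
) -> dict:
    """Permutation test: one-sided p = (1 + #{I_sim >= I_obs}) / (1 + n_sim)."""
    if n_sim < 1:
        raise ConfigurationError("n_sim must be >= 1")
    observed = morans_i(values, weights)
    values = np.asarray(values, dtype=float)
    z = values - values.mean()
    denom = float(z @ z)
    W = weights.dense()
    s0 = W.sum()
    n = values.size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20]))
    sims = np.empty(n_sim)
    for s in range(n_sim):
        zp = rng.permutation(z)
        sims[s] = (n / s0) * (zp @ W @ zp) / denom
    p = (1.0 + np.sum(sims >= observed)) / (1.0 + n_sim)
    return {
        "I_observed": observed,
        "p": float(p),
        "n_sim": int(n_sim),
        "expected_null": -1.0 / (n - 1),
        "sim_mean": float(sims.mean()),
    }


# ---------------------------------------------------------------------------
# residual correlation across models


def residual_correlation(fits: dict[str, learners.ModelFit], sites: SiteTable) -> pd.DataFrame:
    """Pairwise Pearson r between model residuals (log scale)."""
    if len(fits) < 2:
        raise ConfigurationError("need at least 2 fits")
    observed = sites.log_response
    residuals = {
        name: learners.predict_sites(fit, sites) - observed for name, fit in fits.items()
    }
    names = list(residuals)
    mat = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            r = float(stats.pearsonr(residuals[a], residuals[names[j]])[0])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# environmental novelty (PCA distance)


@dataclass
class NoveltyMap:
    """Grid of environmental distance (PC units) from the sampled sites."""

    grid: GridMap
    n_ref: int
    n_pc: int
    k_near: int
    seed: int
    variance_fraction: np.ndarray  # per-PC fraction, all components
    retained_variance: float  # sum over the first n_pc


def _pca_eig(ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA by eigen-decomposition of the reference covariance; components
    sign-fixed so each one's largest-magnitude loading is positive."""
    centered = ref - ref.mean(axis=0)
    cov = centered.T @ centered / (len(ref) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[lead, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return eigval, eigvec


def env_pc_distance(
    stack: CovariateStack,
    sites: SiteTable,
    n_ref: int = NOVELTY_DEFAULTS["n_ref"],
    n_pc: int = NOVELTY_DEFAULTS["n_pc"],
    k_near: int = NOVELTY_DEFAULTS["k_near"],
    seed: int = 0,
    variables: list[str] | None = None,
) -> NoveltyMap:
    """Average Euclidean distance, in the first ``n_pc`` principal
    components, from every cell to its ``k_near`` nearest site projections.

    Covariates are z-scored using reference-point statistics; the PCA is fit
    on ``n_ref`` cells sampled uniformly without replacement over non-missing
    cells (all cells, deterministically, when ``n_ref`` covers them).
    """
    variables = sorted(variables) if variables is not None else sorted(
        set(stack.layer_names) & set(sites.covariate_names)
    )
    if not variables:
        raise ConfigurationError("stack and sites share no covariates")
    if n_pc < 1 or n_pc > len(variables):
        raise ConfigurationError(f"n_pc must be in 1..{len(variables)}, got {n_pc}")
    k_near = min(k_near, sites.n)
    cells = stack.table(variables).to_numpy(dtype=float)
    if n_ref >= len(cells):
        ref = cells  # reference budget covers every cell: use them all, exactly once
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 30]))
        ref = cells[rng.choice(len(cells), size=n_ref, replace=False)]

    mean = ref.mean(axis=0)
    scale = ref.std(axis=0)
    scale[scale == 0] = 1.0  # constant layer carries no information

    eigval, eigvec = _pca_eig((ref - mean) / scale)
    total = eigval.sum()
    variance_fraction = eigval / total if total > 0 else np.zeros_like(eigval)

    project = lambda X: ((X - mean) / scale) @ eigvec[:, :n_pc]
    cell_pc = project(cells)
    site_pc = project(sites.covariate_matrix(variables))

    dist = cdist(cell_pc, site_pc)
    dist.sort(axis=1)
    avg = dist[:, :k_near].mean(axis=1)

    values = np.zeros(stack.geometry.shape)
    values.ravel()[stack.mask.ravel().nonzero()[0]] = avg
    grid = GridMap(
        values, stack.mask.copy(), stack.geometry, name="novelty", units="PC units"
    )
    return NoveltyMap(
        grid=grid,
        n_ref=int(n_ref),
        n_pc=int(n_pc),
        k_near=int(k_near),
        seed=int(seed),
        variance_fraction=variance_fraction,
        retained_variance=float(variance_fraction[:n_pc].sum()),
    )


def apply_novelty_mask(
    pred: GridMap, novelty: NoveltyMap, threshold: float = NOVELTY_THRESHOLD_DEFAULT
) -> GridMap:
    """Mask prediction cells whose novelty distance exceeds the threshold;
    all other cells pass through unchanged."""
    ngrid = novelty.grid
    if ngrid.geometry != pred.geometry:
        raise GeometryError("prediction and novelty maps disagree on geometry")
    out = pred.copy()
    too_far = ngrid.mask & (ngrid.values > threshold)
    out.mask = pred.mask & ~too_far
    out.values[~out.mask] = 0.0
    out.name = f"{pred.name}_masked"
    return out


# ---------------------------------------------------------------------------
# NPP detrending


def npp_detrend(pred: GridMap, npp: GridMap) -> GridMap:
    """Residuals of an OLS line of prediction on NPP over joint valid cells."""
    if pred.geometry != npp.geometry:
        raise GeometryError("prediction and NPP maps disagree on geometry")
    joint = pred.mask & npp.mask
    if joint.sum() < 3:
        raise ConfigurationError("need at least 3 joint non-missing cells")
    x = npp.values[joint]
    y = pred.values[joint]
    if x.std() == 0:
        raise DegeneracyError("constant NPP: detrending undefined")
    slope, intercept = np.polyfit(x, y, 1)
    values = np.zeros(pred.geometry.shape)
    values[joint] = y - (slope * x + intercept)
    return GridMap(values, joint, pred.geometry, name=f"{pred.name}_npp_residual", units=pred.units)


# ---------------------------------------------------------------------------
# variable clustering for the importance display


@dataclass
class VariableClustering:
    variables: list[str]
    distance: pd.DataFrame  # 1 - |r|
    linkage_matrix: np.ndarray  # scipy average-linkage encoding
    excluded: list[str]  # constant covariates, flagged and left out


def variable_cluster(sites: SiteTable, variables: list[str] | None = None) -> VariableClustering:
    """Average-linkage hierarchy over covariates at distance 1 - |Pearson r|."""
    variables = list(variables) if variables is not None else sites.covariate_names
    X = sites.covariate_matrix(variables)
    sd = X.std(axis=0)
    excluded = [v for v, s in zip(variables, sd) if s == 0]
    kept = [v for v, s in zip(variables, sd) if s > 0]
    if len(kept) < 2:
        raise ConfigurationError("need at least 2 non-constant covariates")
    Xk = X[:, sd > 0]
    corr = np.corrcoef(Xk, rowvar=False)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="average")
    return VariableClustering(
        variables=kept,
        distance=pd.DataFrame(dist, index=kept, columns=kept),
        linkage_matrix=Z,
        excluded=excluded,
    )
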