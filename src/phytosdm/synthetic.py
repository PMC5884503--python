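"""Synthetic landscapes and site datasets with the covariate structure the
analysis assumes: a deterministic coast-distance gradient, blocks of highly
inter-correlated temperature and precipitation variables, soil layers with a
texture simplex, an NPP layer, and a log-scale proxy response.

Spatially structured covariates are low-rank Gaussian random fields:
Gaussian-smoothed white noise with a configurable range, standardized to
unit variance.  Within-block correlation rho is induced by mixing one shared
latent field with an independent field per member,

    member_i = sqrt(rho) * shared + sqrt(1 - rho) * independent_i,

so that corr(member_i, member_j) = rho for i != j by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .data_model import CovariateStack, GridGeometry, SiteTable
from .errors import ConfigurationError, SamplingError

# fraction of the shared temperature/precipitation latent carried by the
# coastal gradient, so climate blocks correlate with coast distance as the
# emulated geography requires
_TEMP_COAST_MIX = 0.6
_PRECIP_COAST_MIX = 0.4
_NPP_COAST_MIX = 0.5


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic landscape generator."""

    rows: int = 50
    cols: int = 50
    cell_size: float = 1000.0  # map units (m); coast_distance = col * cell_size
    n_temperature: int = 8
    n_precipitation: int = 8
    n_soil_extra: int = 8
    block_correlation: float = 0.7  # within-block correlation, in [0, 1)
    field_range: float = 5000.0  # spatial range of random fields, map units
    response_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "temp_01": -0.8,
            "temp_02": -0.4,
            "precip_01": 0.4,
            "coast_distance": -0.5,
            "ph": 0.2,
        }
    )
    nonlinear_response: bool = False
    noise_sd: float = 0.3  # log-scale site noise
    baseline_log: float = -1.5  # baseline ln(phytolith %)
    seed: int = 0
    coastal_oversampling: float = 0.0  # >0 biases site sampling toward the coast

    def validate(self) -> None:
        if self.rows < 4 or self.cols < 4:
            raise ConfigurationError(f"grid must be at least 4x4, got {self.rows}x{self.cols}")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if not (0.0 <= self.block_correlation < 1.0):
            raise ConfigurationError(
                f"block_correlation must be in [0, 1), got {self.block_correlation}"
            )
        if min(self.n_temperature, self.n_precipitation, self.n_soil_extra) < 0:
            raise ConfigurationError("block sizes must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.field_range <= 0:
            raise ConfigurationError("field_range must be positive")
        unknown = set(self.response_coefficients) - set(self.covariate_names())
        if unknown:
            raise ConfigurationError(
                f"response coefficients name unknown covariates: {sorted(unknown)}"
            )

    def covariate_names(self) -> list[str]:
        names = ["coast_distance"]
        names += [f"temp_{i + 1:02d}" for i in range(self.n_temperature)]
        names += [f"precip_{i + 1:02d}" for i in range(self.n_precipitation)]
        names += ["ph", "bulk_density", "sand", "silt", "clay"]
        names += [f"soil_{i + 1:02d}" for i in range(self.n_soil_extra)]
        names += ["npp"]
        return names


def _random_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Unit-variance Gaussian random field: smoothed white noise, standardized."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # sigma so large the field is flat; fall back to white noise
        return white - white.mean()
    return (smooth - smooth.mean()) / sd


def _block(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sigma: float,
    n_members: int,
    rho: float,
    shared: np.ndarray,
) -> list[np.ndarray]:
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    return [a * shared + b * _random_field(rng, shape, sigma) for _ in range(n_members)]


def generate_landscape(config: LandscapeConfig) -> CovariateStack:
    """Generate the covariate stack; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    shape = (config.rows, config.cols)
    sigma = config.field_range / config.cell_size
    geom = GridGeometry(rows=config.rows, cols=config.cols, cell_size=config.cell_size)

    layers: dict[str, np.ndarray] = {}

    # deterministic coastal gradient: 0 at the left edge, increasing eastward
    col_idx = np.tile(np.arange(config.cols, dtype=float), (config.rows, 1))
    coast = col_idx * config.cell_size
    layers["coast_distance"] = coast
    coast_std = (
        (coast - coast.mean()) / coast.std() if coast.std() > 0 else np.zeros(shape)
    )

    def coast_mixed_latent(mix: float, sign: float = 1.0) -> np.ndarray:
        latent = _random_field(rng, shape, sigma)
        return sign * mix * coast_std + np.sqrt(1.0 - mix**2) * latent

    temp_shared = coast_mixed_latent(_TEMP_COAST_MIX)  # hotter inland
    for i, member in enumerate(
        _block(rng, shape, sigma, config.n_temperature, config.block_correlation, temp_shared)
    ):
        layers[f"temp_{i + 1:02d}"] = 15.0 + 5.0 * member

    precip_shared = coast_mixed_latent(_PRECIP_COAST_MIX, sign=-1.0)  # wetter at coast
    for i, member in enumerate(
        _block(rng, shape, sigma, config.n_precipitation, config.block_correlation, precip_shared)
    ):
        layers[f"precip_{i + 1:02d}"] = np.maximum(600.0 + 250.0 * member, 0.0)

    layers["ph"] = np.clip(6.5 + 0.8 * _random_field(rng, shape, sigma), 4.0, 8.5)
    layers["bulk_density"] = np.clip(1.4 + 0.2 * _random_field(rng, shape, sigma), 0.8, 2.0)

    # soil texture simplex via softmax of three fields: sums to 1 exactly
    texture_fields = np.stack([_random_field(rng, shape, sigma) for _ in range(3)])
    expf = np.exp(texture_fields)
    fractions = expf / expf.sum(axis=0)
    layers["sand"], layers["silt"], layers["clay"] = fractions[0], fractions[1], fractions[2]

    for i in range(config.n_soil_extra):
        layers[f"soil_{i + 1:02d}"] = 10.0 + 4.0 * _random_field(rng, shape, sigma)

    layers["npp"] = np.maximum(
        600.0 + 200.0 * coast_mixed_latent(_NPP_COAST_MIX, sign=-1.0), 0.0
    )

    return CovariateStack(layers, geom)


def sample_sites(
    stack: CovariateStack,
    n: int,
    seed: int,
    coastal_oversampling: float = 0.0,
) -> SiteTable:
    """Sample ``n`` distinct cell-center sites uniformly over non-missing
    cells (optionally biased toward low coast_distance); response empty."""
    if n < 1:
        raise SamplingError("need n >= 1 sites")
    valid = np.flatnonzero(stack.mask.ravel())
    if n > valid.size:
        raise SamplingError(f"requested {n} sites but only {valid.size} non-missing cells")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    if coastal_oversampling > 0 and "coast_distance" in stack:
        coast = stack["coast_distance"].ravel()[valid]
        span = coast.max() - coast.min()
        weights = np.exp(-coastal_oversampling * (coast - coast.min()) / max(span, 1e-12))
        prob = weights / weights.sum()
    else:
        prob = None
    chosen = rng.choice(valid, size=n, replace=False, p=prob)
    chosen.sort()
    rows, cols = np.unravel_index(chosen, stack.geometry.shape)
    geom = stack.geometry
    xs = geom.x_origin + (cols + 0.5) * geom.cell_size
    ys = geom.y_origin - (rows + 0.5) * geom.cell_size
    frame = stack.values_at(xs, ys)
    frame.insert(0, "site_id", [f"s{i + 1:04d}" for i in range(n)])
    frame.insert(1, "x", xs)
    frame.insert(2, "y", ys)
    return SiteTable(frame)


def simulate_response(sites: SiteTable, config: LandscapeConfig) -> SiteTable:
    """Fill the phytolith response.

    log-phytolith = baseline + sum(coef * standardized covariate)
    (+ optional quadratic nonlinearity) + Normal(0, noise_sd); the stored
    response is the back-transformed percent value, strictly positive.
    """
    config.validate()
    missing = [v for v in config.response_coefficients if v not in sites.frame.columns]
    if missing:
        raise ConfigurationError(f"sites are missing coefficient covariates: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    log_y = np.full(sites.n, float(config.baseline_log))
    for name, coef in config.response_coefficients.items():
        x = sites.frame[name].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        log_y += coef * z
        if config.nonlinear_response:
            # smooth quadratic bend per driver, zero-mean in z
            log_y += 0.3 * coef * (z**2 - 1.0)
    if config.noise_sd > 0:
        log_y += rng.normal(0.0, config.noise_sd, size=sites.n)
    return sites.with_response(np.exp(log_y))


def simulate_dataset(
    config: LandscapeConfig, n_sites: int
) -> tuple[CovariateStack, SiteTable]:
    """Landscape + sampled sites + simulated response in one call."""
    stack = generate_landscape(config)
    sites = sample_sites(
        stack, n_sites, seed=config.seed, coastal_oversampling=config.coastal_oversampling
    )
    return stack, simulate_response(sites, config)
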