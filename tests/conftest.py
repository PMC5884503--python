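import numpy as np
import pandas as pd
import pytest

from phytosdm.data_model import CovariateStack, GridGeometry, SiteTable
from phytosdm.synthetic import LandscapeConfig, generate_landscape, sample_sites, simulate_response

# fast learner settings used by unit tests (paper defaults stay the package
# defaults; tests shrink the forest to keep the suite quick)
FAST_RF = dict(n_trees=100)


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(
        rows=30,
        cols=30,
        n_temperature=4,
        n_precipitation=4,
        n_soil_extra=2,
        field_range=3000.0,
        noise_sd=0.25,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_stack(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_sites(small_config, small_stack):
    sites = sample_sites(small_stack, 80, seed=small_config.seed)
    return simulate_response(sites, small_config)


@pytest.fixture()
def toy_sites():
    """Hand-built 12-site table with two covariates and a positive response."""
    rng = np.random.default_rng(42)
    n = 12
    frame = pd.DataFrame(
        {
            "site_id": [f"t{i:02d}" for i in range(n)],
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        }
    )
    frame["phytolith_pct"] = np.exp(0.5 * frame["a"] - 0.2 * frame["b"])
    return SiteTable(frame)


def linear_sites(n, p, coefs, noise_sd, seed, intercept=0.0):
    """Sites whose log response is an exact linear function of iid normal
    covariates plus optional noise; used as a known-truth generator."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    names = [f"v{j:02d}" for j in range(p)]
    log_y = intercept + X @ np.asarray(coefs)
    if noise_sd > 0:
        log_y = log_y + rng.normal(0, noise_sd, n)
    frame = pd.DataFrame(X, columns=names)
    frame.insert(0, "site_id", [f"s{i:04d}" for i in range(n)])
    frame.insert(1, "x", rng.uniform(0, 1e4, n))
    frame.insert(2, "y", rng.uniform(0, 1e4, n))
    frame["phytolith_pct"] = np.exp(log_y)
    return SiteTable(frame)


def tiny_stack(layer_values: dict, cell_size=100.0, mask=None):
    """Build a stack from small 2-D arrays given as lists."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in layer_values.items()}
    rows, cols = next(iter(arrays.values())).shape
    geom = GridGeometry(rows=rows, cols=cols, x_origin=0.0, y_origin=rows * cell_size,
                        cell_size=cell_size)
    return CovariateStack(arrays, geom, mask=mask)
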