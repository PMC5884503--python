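"""Configuration, orchestration, and the run manifest.

One human-readable YAML config drives the whole analysis:
screen -> fit -> CV -> ensemble -> predict -> novelty mask -> diagnostics
-> accumulation.  Every analysis constant (k=5, 2000 trees, mtry=2,
n_ref=3000, n_pc=3, k_near=3, threshold=3, n_sim=999, 0.30%) appears as a
config default, never a hard-coded literal in the stage code.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accumulation as accumulation_mod
from . import diagnostics, ensemble, learners, synthetic
from .data_model import SiteTable, read_sites, read_stack, write_map, write_sites, write_stack
from .data_model import correlation_screen
from .errors import PhytoSDMError, PipelineError

log = logging.getLogger("phytosdm")

DEFAULT_CONFIG: dict = {
    "data": {
        "sites": None,  # CSV path; null -> simulate
        "stack": None,  # stack directory; null -> simulate
        "synthetic": {
            "rows": 40,
            "cols": 40,
            "cell_size": 1000.0,
            "n_temperature": 8,
            "n_precipitation": 8,
            "n_soil_extra": 8,
            "block_correlation": 0.7,
            "field_range": 5000.0,
            "nonlinear_response": False,
            "noise_sd": 0.3,
            "baseline_log": -1.5,
            "seed": 0,
            "n_sites": 120,
        },
    },
    "screen": {
        "response": "phytolith_pct",
        "restrict_covariate": "coast_distance",
        "restrict_max": 75000.0,  # the restricted-range variant (75 km in m)
    },
    "learners": {
        "random_forest": {"n_trees": 2000, "mtry": 2, "min_node_size": 5},
        "lasso": {"cv_folds": 10, "n_lambdas": 100},
        "gam": {"variables": None, "basis_size": 10},
    },
    "cv": {"k": 5, "seed": 0},
    "ensemble": {"back_transform": True},
    "novelty": {"n_ref": 3000, "n_pc": 3, "k_near": 3, "threshold": 3.0, "seed": 0},
    "diagnostics": {"knn_k": 5, "n_sim": 999, "seed": 0},
    "accumulation": {
        "cover": 0.75,
        "biomass": 200.0,
        "production": 0.04,
        "bulk_density": 1.5,
        "depth": 60.0,
        "threshold": 0.003,
        "dissolution": 0.0,
    },
    "output_dir": "phytosdm_out",
}

KNOWN_LEARNERS = ("random_forest", "lasso", "gam")


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None) -> dict:
    """Defaults merged with the YAML file at ``path`` (if any)."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        config = _merge(config, user)
    return config


def validate_config(path_or_config: str | Path | dict) -> list[str]:
    """Schema and range checks; returns a list of problems (empty = valid)."""
    if isinstance(path_or_config, dict):
        config = _merge(default_config(), path_or_config)
    else:
        try:
            config = load_config(path_or_config)
        except Exception as exc:
            return [f"cannot read config: {exc}"]
    problems: list[str] = []

    def check(ok: bool, message: str) -> None:
        if not ok:
            problems.append(message)

    syn = config["data"]["synthetic"]
    check(syn["rows"] >= 4 and syn["cols"] >= 4, "data.synthetic.rows/cols: grid must be >= 4x4")
    check(0 <= syn["block_correlation"] < 1, "data.synthetic.block_correlation: must be in [0, 1)")
    check(syn["noise_sd"] >= 0, "data.synthetic.noise_sd: must be nonnegative")
    check(syn["n_sites"] >= 1, "data.synthetic.n_sites: must be >= 1")
    for name in config["learners"]:
        check(name in KNOWN_LEARNERS, f"learners.{name}: unknown learner name")
    rf = config["learners"].get("random_forest", {})
    if rf:
        check(rf.get("n_trees", 1) >= 1, "learners.random_forest.n_trees: must be >= 1")
        check(rf.get("mtry", 1) >= 1, "learners.random_forest.mtry: must be >= 1")
    check(config["cv"]["k"] >= 2, "cv.k: must be >= 2")
    nov = config["novelty"]
    check(nov["n_ref"] >= 1, "novelty.n_ref: must be >= 1")
    check(nov["n_pc"] >= 1, "novelty.n_pc: must be >= 1")
    check(nov["k_near"] >= 1, "novelty.k_near: must be >= 1")
    check(nov["threshold"] >= 0, "novelty.threshold: must be nonnegative")
    diag = config["diagnostics"]
    check(diag["n_sim"] >= 1, "diagnostics.n_sim: must be >= 1")
    check(diag["knn_k"] >= 1, "diagnostics.knn_k: must be >= 1")
    acc = config["accumulation"]
    try:
        accumulation_mod.AccumulationScenario(**acc).validate()
    except (PhytoSDMError, TypeError) as exc:
        problems.append(f"accumulation: {exc}")
    return problems


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _landscape_config(config: dict) -> synthetic.LandscapeConfig:
    syn = {k: v for k, v in config["data"]["synthetic"].items() if k != "n_sites"}
    return synthetic.LandscapeConfig(**syn)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"not JSON serializable: {type(value)}")


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run every stage and return the manifest (also written to
    ``manifest.json``).  Any stage failure aborts with the stage named."""
    config = _merge(default_config(), config)
    problems = validate_config(config)
    if problems:
        raise PipelineError("config", "; ".join(problems))
    out = Path(output_dir or config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {"stages": [], "artifacts": artifacts, "config": config}

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    # ---- data ---------------------------------------------------------
    try:
        stage("data")
        if config["data"]["sites"] is not None:
            sites = read_sites(config["data"]["sites"])
            stack = read_stack(config["data"]["stack"]) if config["data"]["stack"] else None
        else:
            lconf = _landscape_config(config)
            stack, sites = synthetic.simulate_dataset(lconf, config["data"]["synthetic"]["n_sites"])
        write_sites(sites, out / "sites.csv")
        record(out / "sites.csv")
        if stack is None:
            raise PhytoSDMError("a covariate stack is required (data.stack or synthetic)")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("data", str(exc)) from exc

    # ---- correlation screen ------------------------------------------
    try:
        stage("screen")
        scr = config["screen"]
        full = correlation_screen(sites, response=scr["response"])
        full.insert(0, "subset", "full")
        tables = [full]
        if scr.get("restrict_covariate"):
            restricted = correlation_screen(
                sites,
                response=scr["response"],
                restrict=(scr["restrict_covariate"], float(scr["restrict_max"])),
            )
            restricted.insert(0, "subset", "restricted")
            tables.append(restricted)
        pd.concat(tables).to_csv(out / "correlation_screen.csv", index=False, float_format="%.10g")
        record(out / "correlation_screen.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    # ---- CV + ensemble ------------------------------------------------
    try:
        stage("crossval")
        lconf = config["learners"]
        gam_conf = dict(lconf.get("gam", {}))
        gam_vars = gam_conf.pop("variables", None)
        rf_conf = dict(lconf.get("random_forest", {}))
        specs = ensemble.default_learner_specs(
            gam_variables=gam_vars,
            rf_settings=rf_conf,
            lasso_settings=lconf.get("lasso", {}),
            gam_settings=gam_conf,
        )
        specs = {name: specs[name] for name in KNOWN_LEARNERS if name in lconf}
        model = ensemble.fit_ensemble(
            sites, specs, k=int(config["cv"]["k"]), seed=int(config["cv"]["seed"])
        )
        cv_payload = model.cv_report.to_dict()
        cv_payload["weights"] = model.weights
        cv_payload["fit_statistics"] = ensemble.ensemble_fit_statistics(model, sites)
        _write_json(cv_payload, out / "cv_report.json")
        record(out / "cv_report.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("crossval", str(exc)) from exc

    # ---- fits + importance -------------------------------------------
    try:
        stage("importance")
        fits_dir = out / "fits"
        fits_dir.mkdir(exist_ok=True)
        for name, fit in model.fits.items():
            learners.save_fit(fit, fits_dir / f"{name}.joblib")
            table = learners.variable_importance(fit, sites)
            path = out / f"importance_{name}.csv"
            table.frame.to_csv(path, index=False, float_format="%.10g")
            record(path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("importance", str(exc)) from exc

    # ---- prediction + novelty mask -----------------------------------
    try:
        stage("predict")
        pred = ensemble.ensemble_predict(
            model, stack, back_transform_flag=bool(config["ensemble"]["back_transform"])
        )
        write_map(pred, out / "ensemble_prediction.asc")
        record(out / "ensemble_prediction.asc")

        nov_conf = config["novelty"]
        novelty = diagnostics.env_pc_distance(
            stack,
            sites,
            n_ref=int(nov_conf["n_ref"]),
            n_pc=int(nov_conf["n_pc"]),
            k_near=int(nov_conf["k_near"]),
            seed=int(nov_conf["seed"]),
        )
        write_map(novelty.grid, out / "novelty.asc")
        record(out / "novelty.asc")
        masked = diagnostics.apply_novelty_mask(pred, novelty, float(nov_conf["threshold"]))
        write_map(masked, out / "ensemble_prediction_masked.asc")
        record(out / "ensemble_prediction_masked.asc")
        manifest["novelty_retained_variance"] = novelty.retained_variance
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("novelty", str(exc)) from exc

    # ---- spatial diagnostics -----------------------------------------
    try:
        stage("diagnose")
        diag = config["diagnostics"]
        weights = diagnostics.knn_weights(
            sites.coords, k=int(diag["knn_k"]), site_ids=[str(s) for s in sites.site_ids]
        )
        observed = sites.log_response
        moran_report = {}
        for name, fit in model.fits.items():
            residuals = learners.predict_sites(fit, sites) - observed
            moran_report[name] = diagnostics.morans_mc(
                residuals, weights, n_sim=int(diag["n_sim"]), seed=int(diag["seed"])
            )
        _write_json(moran_report, out / "morans.json")
        record(out / "morans.json")

        resid_corr = diagnostics.residual_correlation(model.fits, sites)
        resid_corr.to_csv(out / "residual_correlation.csv", float_format="%.10g")
        record(out / "residual_correlation.csv")

        if "npp" in stack:
            detrended = diagnostics.npp_detrend(pred, stack.as_map("npp"))
            write_map(detrended, out / "npp_detrended.asc")
            record(out / "npp_detrended.asc")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("diagnose", str(exc)) from exc

    # ---- accumulation -------------------------------------------------
    try:
        stage("accumulate")
        scenario = accumulation_mod.AccumulationScenario(**config["accumulation"])
        _write_json(accumulation_mod.time_to_threshold(scenario), out / "accumulation.json")
        record(out / "accumulation.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("accumulate", str(exc)) from exc

    _write_json(manifest, out / "manifest.json")
    return manifest
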