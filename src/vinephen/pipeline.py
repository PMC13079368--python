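"""Reproducible orchestration: simulate -> extract -> train -> fit-growth -> summarize.

A run is driven by a YAML config (defaults filled, unknown keys rejected),
a global seed from which per-stage seeds are derived by stable hashing, and
an output directory. Every stage writes plain-text artifacts (CSV/JSON) plus
a final JSON manifest with the config hash, per-file SHA-256 digests,
software versions, seeds and timestamps. Stages are resumable: a stage whose
outputs already exist is skipped when ``resume`` is set.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomass_regression import ALGORITHMS, RegressionSpec, run_regression
from .canopy_features import (
    VIEWS, GsiConfig, build_feature_table, load_patch, save_patch,
)
from .growth_bayes import (
    DECAY_MODES, MCMCConfig, convergence, fit_hierarchical, posterior_summaries,
)
from .synthcanopy import (
    FieldDesign, SeriesDesign, simulate_canopy_patch, simulate_feature_dataset,
    simulate_field_design, simulate_growth_series, state_from_biomass,
)

logger = logging.getLogger("vinephen.pipeline")

STAGES = ("simulate", "extract", "train", "fit_growth", "summarize")


class ConfigError(ValueError):
    """Itemized configuration problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid config:\n  - " + "\n  - ".join(self.problems))


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "vinephen_run",
    "stages": list(STAGES),
    "simulate": {
        # small-field defaults keep a full run desk-scale; the study-scale
        # counts are available by overriding these blocks
        "field": {"n_genotypes": 4, "n_treatments": 2, "n_replicates": 2,
                  "n_years": 1},
        "series": {"n_genotypes": 4, "n_plants": 4, "n_replicates": 2},
        "sigma_obs": 13.0,
        "n_patch_plants": 8,
        "pixel_size_m": 0.02,
    },
    "extract": {
        "views": list(VIEWS),
        "gsi_a": 0.635,
        "optimize_gsi": False,
        "ground_percentile": 5.0,
    },
    "train": {
        "algorithm": "SVR",
        "view": "COMBINED",
        "train_fraction": 0.8,
        "cv_folds": 5,
        "svr_C_grid": [1, 5, 10, 50, 100],
        "svr_gamma_grid": [0.01, 0.05, 0.1, 0.5, 1],
        "with_shap": True,
    },
    "fit_growth": {
        "decay_mode": "as_printed",
        "n_chains": 2,
        "n_iterations": 600,
        "n_warmup": 300,
    },
    "summarize": {"interval_level": 0.99, "band_level": 0.95},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _merge(defaults: dict, override: dict, path: str, problems: list) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (override or {}).items():
        if key not in defaults:
            problems.append(f"unknown key {path + key!r}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, f"{path}{key}.", problems)
        else:
            out[key] = val
    return out


def validate_config(config=None) -> dict:
    """Normalize a config mapping or YAML file path against the defaults.

    Fills defaults, rejects unknown keys and out-of-range values with an
    itemized :class:`ConfigError`, and returns the normalized dict.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text) or {}
    if not isinstance(config, dict):
        raise ConfigError(["config root must be a mapping"])
    problems: list = []
    cfg = _merge(DEFAULT_CONFIG, config, "", problems)
    if not 0.0 < cfg["train"]["train_fraction"] < 1.0:
        problems.append("train.train_fraction must lie strictly between 0 and 1")
    if cfg["train"]["algorithm"] not in ALGORITHMS:
        problems.append(f"train.algorithm must be one of {ALGORITHMS}")
    if cfg["train"]["view"] not in VIEWS:
        problems.append(f"train.view must be one of {VIEWS}")
    if cfg["fit_growth"]["decay_mode"] not in DECAY_MODES:
        problems.append(f"fit_growth.decay_mode must be one of {DECAY_MODES}")
    if cfg["fit_growth"]["n_warmup"] >= cfg["fit_growth"]["n_iterations"]:
        problems.append("fit_growth.n_warmup must be below n_iterations")
    unknown_stages = set(cfg["stages"]) - set(STAGES)
    if unknown_stages:
        problems.append(f"unknown stages: {sorted(unknown_stages)}")
    if not 0.0 <= cfg["extract"]["gsi_a"] <= 1.0:
        problems.append("extract.gsi_a must lie in [0, 1]")
    if problems:
        raise ConfigError(problems)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _versions() -> dict:
    import sklearn
    import xgboost

    return {
        "vinephen": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------


def _stage_simulate(cfg, out: Path, seed: int) -> list:
    sim = cfg["simulate"]
    field = FieldDesign(**sim["field"])
    tables = simulate_field_design(field, seed=seed)
    tables.plants.to_csv(out / "plants.csv", index=False)
    tables.sampling.to_csv(out / "sampling.csv", index=False)
    features, biomass = simulate_feature_dataset(field, seed=seed)
    features.to_csv(out / "features.csv", index=False)
    biomass.to_csv(out / "biomass.csv", index=False)
    series = simulate_growth_series(
        design=SeriesDesign(**sim["series"]), sigma_obs=sim["sigma_obs"], seed=seed
    )
    series.to_csv(out / "series.csv", index=False)
    # render raster patches for a subset of sampled plants, all three views
    patch_dir = out / "patches"
    rng = np.random.default_rng(seed)
    chosen = biomass.sample(
        n=min(sim["n_patch_plants"], len(biomass)), random_state=int(rng.integers(2**31))
    )
    written = []
    for _, rec in chosen.iterrows():
        state = state_from_biomass(
            rec["plant_id"], rec["genotype_id"], rec["shoot_dry_weight_g"],
            dap=rec["dap"], treatment=rec["treatment"], year=rec["year"],
        )
        for view in VIEWS:
            patch = simulate_canopy_patch(
                state, view, pixel_size_m=sim["pixel_size_m"],
                seed=int(rng.integers(2**31)),
            )
            patch.metadata.pop("truth", None)  # on-disk patches carry no oracle
            stem = f"{rec['plant_id']}_{view}"
            save_patch(patch, patch_dir, stem)
            written.append(stem)
    (out / "patch_index.json").write_text(json.dumps(written))
    return ["plants.csv", "sampling.csv", "features.csv", "biomass.csv",
            "series.csv", "patch_index.json"]


def _stage_extract(cfg, out: Path, seed: int) -> list:
    ext = cfg["extract"]
    stems = json.loads((out / "patch_index.json").read_text())
    patches = [load_patch(out / "patches", stem) for stem in stems]
    gsi = GsiConfig(a=ext["gsi_a"], optimize=ext["optimize_gsi"])
    table = build_feature_table(
        patches, views=tuple(ext["views"]), gsi=gsi,
        ground_percentile=ext["ground_percentile"],
    )
    table.to_csv(out / "extracted_features.csv", index=False)
    return ["extracted_features.csv"]


def _stage_train(cfg, out: Path, seed: int) -> list:
    tr = cfg["train"]
    features = pd.read_csv(out / "features.csv")
    biomass = pd.read_csv(out / "biomass.csv")
    spec = RegressionSpec(
        algorithm=tr["algorithm"], seed=seed,
        train_fraction=tr["train_fraction"], cv_folds=tr["cv_folds"],
        svr_C_grid=tuple(tr["svr_C_grid"]), svr_gamma_grid=tuple(tr["svr_gamma_grid"]),
    )
    result = run_regression(features, biomass, spec, tr["view"], with_shap=tr["with_shap"])
    evaluation = {
        "view": result["view"], "algorithm": result["algorithm"],
        "overall": result["overall"],
        "subgroups": result["subgroups"].to_dict(orient="records"),
    }
    (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2, default=float))
    result["cv_record"].assign(
        params=result["cv_record"]["params"].map(json.dumps)
    ).to_csv(out / "cv_record.csv", index=False)
    if "shap" in result:
        shap = result["shap"]
        table = shap.values.copy()
        table.insert(0, "baseline", shap.baseline)
        table.to_csv(out / "shap.csv", index=False)
        return ["evaluation.json", "cv_record.csv", "shap.csv"]
    return ["evaluation.json", "cv_record.csv"]


def _stage_fit_growth(cfg, out: Path, seed: int) -> list:
    fg = cfg["fit_growth"]
    series = pd.read_csv(out / "series.csv")
    mcmc = MCMCConfig(
        n_chains=fg["n_chains"], n_iterations=fg["n_iterations"],
        n_warmup=fg["n_warmup"], seed=seed,
    )
    draws = fit_hierarchical(series, mcmc=mcmc, decay_mode=fg["decay_mode"])
    draws.to_frame().to_csv(out / "draws.csv", index=False)
    conv = convergence(draws)
    conv.table.to_csv(out / "convergence.csv", index=False)
    meta = {"decay_mode": fg["decay_mode"], "genotypes": list(draws.genotypes),
            "n_retained": draws.n_retained, "max_rhat": conv.max_rhat}
    (out / "fit_meta.json").write_text(json.dumps(meta, default=float))
    return ["draws.csv", "convergence.csv", "fit_meta.json"]


def _stage_summarize(cfg, out: Path, seed: int) -> list:
    sm = cfg["summarize"]
    long = pd.read_csv(out / "draws.csv")
    meta = json.loads((out / "fit_meta.json").read_text())
    from .growth_bayes import PosteriorDraws

    names = tuple(long["parameter"].unique())
    nc = long["chain"].nunique()
    nd = long["draw"].nunique()
    arr = (
        long.pivot_table(index=["chain", "draw"], columns="parameter", values="value")
        .loc[:, list(names)]
        .to_numpy()
        .reshape(nc, nd, len(names))
    )
    draws = PosteriorDraws(
        array=arr, names=names, genotypes=tuple(meta["genotypes"]),
        decay_mode=meta["decay_mode"],
    )
    series = pd.read_csv(out / "series.csv")
    grid = np.linspace(series["t"].min(), series["t"].max(), 60)
    params, curves = posterior_summaries(
        draws, dap_grid=grid, interval_level=sm["interval_level"],
        band_level=sm["band_level"],
    )
    params.to_csv(out / "posterior_params.csv", index=False)
    curves.to_csv(out / "posterior_curves.csv", index=False)
    return ["posterior_params.csv", "posterior_curves.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "train": _stage_train,
    "fit_growth": _stage_fit_growth,
    "summarize": _stage_summarize,
}

_STAGE_INPUTS = {
    "simulate": [],
    "extract": ["patch_index.json"],
    "train": ["features.csv", "biomass.csv"],
    "fit_growth": ["series.csv"],
    "summarize": ["draws.csv", "fit_meta.json", "series.csv"],
}

_STAGE_OUTPUTS = {
    "simulate": ["plants.csv", "sampling.csv", "features.csv", "biomass.csv",
                 "series.csv", "patch_index.json"],
    "extract": ["extracted_features.csv"],
    "train": ["evaluation.json", "cv_record.csv"],
    "fit_growth": ["draws.csv", "convergence.csv", "fit_meta.json"],
    "summarize": ["posterior_params.csv", "posterior_curves.csv"],
}


def run_pipeline(config=None, resume: bool = False) -> dict:
    """Execute the configured stages in dependency order; write the manifest.

    Raises :class:`StageError` on the first failing stage (partial outputs
    are retained). Returns the manifest dict, also written to
    ``<out_dir>/manifest.json`` after the last stage.
    """
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    normalized = yaml.safe_dump(cfg, sort_keys=True)
    (out / "config.yaml").write_text(normalized)
    config_hash = hashlib.sha256(normalized.encode()).hexdigest()
    manifest = {
        "config_hash": config_hash, "seed": cfg["seed"], "versions": _versions(),
        "stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stages = [s for s in STAGES if s in cfg["stages"]]
    for stage in stages:
        for dep in _STAGE_INPUTS[stage]:
            if not (out / dep).exists():
                raise ConfigError(
                    [f"stage {stage!r} needs {dep}, which is missing from {out}"]
                )
        seed = stage_seed(cfg["seed"], stage)
        if resume and all((out / name).exists() for name in _STAGE_OUTPUTS[stage]):
            logger.info("stage %s: outputs present, resumed from disk", stage)
            manifest["stages"][stage] = {
                "seed": seed, "resumed": True, "inputs": _STAGE_INPUTS[stage],
                "outputs": {n: _sha256(out / n) for n in _STAGE_OUTPUTS[stage]},
            }
            continue
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](cfg, out, seed)
        except Exception as exc:
            logger.error("stage %s failed (outputs so far kept in %s)", stage, out)
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "seed": seed,
            "seconds": round(time.time() - t0, 3),
            "inputs": _STAGE_INPUTS[stage],
            "outputs": {name: _sha256(out / name) for name in outputs},
        }
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
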