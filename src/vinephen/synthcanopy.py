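"""Synthetic field designs, canopy raster patches, biomass and growth series.

Emulates the data-generating structure of a two-year staked-yam trial: a
split-plot randomized complete block design (fertilizer on main plots,
genotype on subplots), per-plant 1 x 1 m RGB + DEM patches rendered at three
view sets (oblique 60 deg, nadir 90 deg, combined) with view-dependent height
bias and occlusion dropout, an allometric feature-to-biomass link, and
growth time series drawn from the Richards-with-decay curve with Gaussian
observation noise and a hierarchical genotype structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from shapely.geometry import box

from .canopy_features import PlantPatch
from .growth_bayes import GrowthParams, PopulationHyper, growth_curve

logger = logging.getLogger("vinephen.synthcanopy")


class InvalidDesignError(ValueError):
    pass


class InvalidCoefsError(ValueError):
    pass


# --------------------------------------------------------------------------
# field design and plant states
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldDesign:
    """Split-plot RCBD trial layout. Defaults reproduce the study design:
    12 genotypes x 2 fertilizer treatments x 3 blocks = 72 plots of 3 x 3 m
    with 16 plants at 1 m spacing; 4 plants destructively sampled per plot at
    each of 2 stages in each of 2 years."""

    n_genotypes: int = 12
    n_treatments: int = 2
    n_replicates: int = 3
    plot_size_m: float = 3.0
    plant_spacing_m: float = 1.0
    n_sampling_times: int = 2
    plants_sampled_per_plot: int = 4
    n_years: int = 2
    sampling_dap: tuple = (60, 120)

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_treatments", "n_replicates",
                     "n_sampling_times", "plants_sampled_per_plot", "n_years"):
            if getattr(self, name) < 1:
                raise InvalidDesignError(f"{name} must be >= 1")
        side = self.plot_size_m / self.plant_spacing_m
        if abs(side - round(side)) > 1e-9:
            raise InvalidDesignError(
                "plot_size_m / plant_spacing_m must be an integer (square planting grid)"
            )
        if len(self.sampling_dap) != self.n_sampling_times:
            raise InvalidDesignError("sampling_dap must list one DAP per sampling time")
        if self.n_sampling_times * self.plants_sampled_per_plot > self.plants_per_plot:
            raise InvalidDesignError("destructive sampling exceeds plants per plot")

    @property
    def plants_per_plot(self) -> int:
        # plants sit on a (side + 1) x (side + 1) grid including plot edges:
        # a 3 x 3 m plot at 1 m spacing holds 16 plants
        return (int(round(self.plot_size_m / self.plant_spacing_m)) + 1) ** 2

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * self.n_treatments * self.n_replicates


TREATMENTS = ("fertilized", "unfertilized")


class FieldTables(NamedTuple):
    plants: pd.DataFrame
    sampling: pd.DataFrame


def simulate_field_design(design: FieldDesign, seed: int = 0) -> FieldTables:
    """Randomize the split-plot RCBD and draw the destructive-sampling plan.

    ``plants`` holds one row per plant per year (plot, block, treatment on
    the main plot, genotype on the subplot). ``sampling`` lists the
    destructively harvested plants: ``plants_sampled_per_plot`` per plot per
    sampling time per year, never re-sampling a plant within a year.
    """
    rng = np.random.default_rng(seed)
    treatments = [TREATMENTS[i % len(TREATMENTS)] for i in range(design.n_treatments)]
    genotypes = [f"g{i + 1:02d}" for i in range(design.n_genotypes)]
    plant_rows, sample_rows = [], []
    for year in range(1, design.n_years + 1):
        plot_no = 0
        for block in range(1, design.n_replicates + 1):
            main_order = rng.permutation(len(treatments))
            for tr_idx in main_order:
                sub_order = rng.permutation(len(genotypes))
                for g_idx in sub_order:
                    plot_no += 1
                    plot_id = f"y{year}_p{plot_no:03d}"
                    plant_ids = []
                    for p in range(1, design.plants_per_plot + 1):
                        pid = f"{plot_id}_{p:02d}"
                        plant_ids.append(pid)
                        plant_rows.append(
                            {"plant_id": pid, "plot_id": plot_id, "year": year,
                             "block": block, "treatment": treatments[tr_idx],
                             "genotype_id": genotypes[g_idx], "position": p}
                        )
                    chosen = rng.choice(
                        plant_ids,
                        size=design.n_sampling_times * design.plants_sampled_per_plot,
                        replace=False,
                    )
                    for s, dap in enumerate(design.sampling_dap):
                        for pid in chosen[
                            s * design.plants_sampled_per_plot:
                            (s + 1) * design.plants_sampled_per_plot
                        ]:
                            sample_rows.append(
                                {"plant_id": pid, "plot_id": plot_id, "year": year,
                                 "block": block, "treatment": treatments[tr_idx],
                                 "genotype_id": genotypes[g_idx],
                                 "sampling_time": s + 1, "dap": dap}
                            )
    plants = pd.DataFrame(plant_rows)
    sampling = pd.DataFrame(sample_rows)
    assert len(plants) == design.n_years * design.n_plots * design.plants_per_plot
    return FieldTables(plants=plants, sampling=sampling)


@dataclass(frozen=True)
class PlantState:
    """Latent per-plant state behind a rendered patch."""

    plant_id: str
    genotype_id: str
    treatment: str = "unfertilized"
    year: int = 1
    dap: float = 60.0
    latent_biomass: float = 50.0  # g/plant
    canopy_height: float = 1.5  # m
    canopy_radius: float = 0.35  # m
    architecture: float = 0.7  # 1 = cylinder, 0 = cone
    leaf_cover: float = 0.85  # fraction of footprint pixels bearing leaves

    def __post_init__(self) -> None:
        if self.latent_biomass < 0 or self.canopy_height < 0 or self.canopy_radius < 0:
            raise ValueError("biomass, height and radius must be non-negative")
        if not 0.0 <= self.leaf_cover <= 1.0:
            raise ValueError("leaf_cover must lie in [0, 1]")
        if not 0.0 <= self.architecture <= 1.0:
            raise ValueError("architecture blend must lie in [0, 1]")


# --------------------------------------------------------------------------
# patch rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchRenderConfig:
    """Rendering knobs: patch geometry, soil/vegetation color model, ridge
    height, and the per-view additive height bias / occlusion dropout that
    emulate view-dependent DEM degradation (combined view least biased)."""

    patch_size_m: float = 1.4
    ground_elevation_m: float = 100.0
    ridge_height_m: float = 0.40
    soil_rgb: tuple = (0.36, 0.28, 0.20)
    veg_rgb: tuple = (0.14, 0.34, 0.10)
    color_sd: float = 0.03
    dem_noise_sd: float = 0.005
    view_bias_m: dict = field(
        default_factory=lambda: {"OBLIQUE60": -0.20, "NADIR90": -0.30, "COMBINED": -0.10}
    )
    view_dropout: dict = field(
        default_factory=lambda: {"OBLIQUE60": 0.20, "NADIR90": 0.30, "COMBINED": 0.08}
    )
    dropout_height_quantile: float = 0.35  # only the lowest canopy pixels can occlude


def simulate_canopy_patch(
    state: PlantState,
    view: str,
    pixel_size_m: float = 0.01,
    seed: int = 0,
    config: PatchRenderConfig | None = None,
) -> PlantPatch:
    """Render one co-registered RGB + DEM patch for a plant state and view.

    The canopy surface is a cylinder/cone blend of height ``canopy_height``
    over a circular footprint; vegetation pixels carry green-shifted
    reflectance, background pixels soil reflectance over a flat 0.40 m ridge.
    The view's additive height bias and low-canopy dropout degrade the DEM
    and mask the way single-view photogrammetry does. Ground truth (footprint
    mask, surface heights) is stored in ``metadata["truth"]``.
    """
    cfg = config or PatchRenderConfig()
    if pixel_size_m <= 0:
        raise ValueError("pixel_size_m must be positive")
    if cfg.patch_size_m < 1.0:
        raise ValueError("patch must cover the 1 x 1 m polygon")
    rng = np.random.default_rng(seed)
    n = int(round(cfg.patch_size_m / pixel_size_m))
    coords = (np.arange(n) + 0.5) * pixel_size_m
    X, Y = np.meshgrid(coords, coords)
    cx = cy = cfg.patch_size_m / 2.0
    r = np.hypot(X - cx, Y - cy)

    if state.canopy_radius > cfg.patch_size_m / 2.0:
        logger.warning(
            "canopy radius %.2f m exceeds the patch half-width; truncated",
            state.canopy_radius,
        )
    footprint = r <= state.canopy_radius
    leafy = footprint & (rng.uniform(size=footprint.shape) < state.leaf_cover)
    if state.latent_biomass <= 0:
        leafy &= False

    # cylinder/cone blend: height profile within the footprint
    with np.errstate(invalid="ignore", divide="ignore"):
        taper = np.where(
            footprint, 1.0 - r / max(state.canopy_radius, 1e-12), 0.0
        )
    surface = state.canopy_height * (state.architecture + (1 - state.architecture) * taper)
    surface = np.where(leafy, surface, 0.0)

    # occlusion dropout of the lowest canopy pixels, per view
    dropped = np.zeros_like(leafy)
    if leafy.any():
        qh = np.quantile(surface[leafy], cfg.dropout_height_quantile)
        low = leafy & (surface <= qh)
        dropped = low & (rng.uniform(size=low.shape) < cfg.view_dropout[view])
    visible = leafy & ~dropped

    ground = cfg.ground_elevation_m + cfg.ridge_height_m
    dem = ground + rng.normal(0.0, cfg.dem_noise_sd, size=(n, n))
    bias = cfg.view_bias_m[view]
    canopy_dem = ground + np.clip(surface + bias, 0.0, None)
    dem = np.where(visible, canopy_dem, dem)

    rgb = np.empty((n, n, 3))
    for c in range(3):
        soil = rng.normal(cfg.soil_rgb[c], cfg.color_sd, size=(n, n))
        veg = rng.normal(cfg.veg_rgb[c], cfg.color_sd, size=(n, n))
        rgb[..., c] = np.where(visible, veg, soil)
    rgb = np.clip(rgb, 0.0, 1.0)

    half = 0.5
    polygon = box(cx - half, cy - half, cx + half, cy + half)
    meta = {
        "plant_id": state.plant_id, "genotype_id": state.genotype_id,
        "treatment": state.treatment, "year": state.year, "dap": state.dap,
        "truth": {
            "footprint": visible, "surface_height": surface,
            "latent_biomass": state.latent_biomass,
        },
    }
    return PlantPatch(
        rgb=rgb, dem=dem, polygon=polygon, pixel_size_m=pixel_size_m,
        view=view, metadata=meta,
    )


# --------------------------------------------------------------------------
# allometric feature -> biomass link
# --------------------------------------------------------------------------


def canopy_volume_proxy(state: PlantState) -> float:
    """Projected leaf area times mean canopy height (m^3)."""
    area = math.pi * state.canopy_radius**2 * state.leaf_cover
    mean_h = state.canopy_height * (state.architecture + (1 - state.architecture) / 3.0)
    return area * mean_h


def allometric_biomass(
    state: PlantState, genotype_coefs, noise_sd: float = 0.0, seed: int = 0
) -> float:
    """Shoot dry weight (g) as a genotype-specific power law of canopy volume.

    ``genotype_coefs = (scale, exponent)``; weight = scale * volume^exponent
    + Normal(0, noise_sd), truncated at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    scale, exponent = genotype_coefs
    if scale < 0 or exponent <= 0:
        raise InvalidCoefsError("allometric coefficients must give non-negative means")
    volume = canopy_volume_proxy(state)
    mean = scale * volume**exponent
    noise = np.random.default_rng(seed).normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    return float(max(mean + noise, 0.0))


# --------------------------------------------------------------------------
# growth series
# --------------------------------------------------------------------------

#: 11 acquisition dates (DAP), 2- and 3-week gaps from week 2 to week 28,
#: spanning both the inflection (~105 DAP) and the decay onset (~193 DAP)
DEFAULT_TIME_POINTS = (14, 35, 56, 77, 98, 119, 140, 154, 168, 182, 196)


@dataclass(frozen=True)
class SeriesDesign:
    """Time-series trial: 12 genotypes x 8 plants x 3 replicates x 11 dates
    = 3,168 biomass records by default."""

    n_genotypes: int = 12
    n_plants: int = 8
    n_replicates: int = 3
    time_points: tuple = DEFAULT_TIME_POINTS

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_plants, self.n_replicates) < 1:
            raise InvalidDesignError("all series factors must be >= 1")
        tp = np.asarray(self.time_points, dtype=float)
        if len(tp) == 0 or np.any(np.diff(tp) <= 0):
            raise InvalidDesignError("time_points must be strictly increasing")

    @property
    def n_records(self) -> int:
        return self.n_genotypes * self.n_plants * self.n_replicates * len(self.time_points)


#: population defaults on the transformed scale (log A, log nu, log k, t_i,
#: log d, t_d): mean biomass plateau ~130 g/plant, inflection ~105 DAP,
#: decay onset ~193 DAP, with moderate between-genotype spread
DEFAULT_POPULATION = PopulationHyper(
    mu0=np.array([math.log(130.0), math.log(1.5), math.log(0.07), 105.0, math.log(0.01), 193.0]),
    sigma0=np.diag(np.array([0.25, 0.35, 0.15, 4.0, 0.20, 4.0]) ** 2),
    sigma_obs=13.0,
)


def draw_genotype_params(
    hyper: PopulationHyper = DEFAULT_POPULATION,
    n_genotypes: int = 12,
    seed: int = 0,
) -> dict:
    """Draw genotype parameter vectors theta_g ~ Normal(mu0, Sigma0) on the
    transformed scale and back-transform to the natural scale."""
    rng = np.random.default_rng(seed)
    phi = rng.multivariate_normal(hyper.mu0, hyper.sigma0, size=n_genotypes)
    return {
        f"g{i + 1:02d}": GrowthParams.from_transformed(phi[i]) for i in range(n_genotypes)
    }


def simulate_growth_series(
    theta_by_genotype: dict | None = None,
    sigma_obs: float = DEFAULT_POPULATION.sigma_obs,
    design: SeriesDesign = SeriesDesign(),
    decay_mode: str = "as_printed",
    seed: int = 0,
    hyper: PopulationHyper | None = None,
    heteroscedastic: bool = False,
) -> pd.DataFrame:
    """Simulate the estimated-biomass series table.

    Each record is ``y = f(t; theta_g) + Normal(0, sd)``; homoscedastic
    ``sd = sigma_obs`` by default, or, in heteroscedastic mode, scaled by
    ``0.5 + f/f_peak`` so noise peaks around maximum shoot biomass. When
    ``theta_by_genotype`` is None, genotype parameters are drawn from
    ``hyper`` (default population).
    """
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be non-negative")
    rng = np.random.default_rng(seed)
    if theta_by_genotype is None:
        theta_by_genotype = draw_genotype_params(
            hyper or DEFAULT_POPULATION, design.n_genotypes, seed=rng.integers(2**31)
        )
    genotypes = sorted(theta_by_genotype)
    if len(genotypes) != design.n_genotypes:
        raise InvalidDesignError(
            f"theta_by_genotype has {len(genotypes)} genotypes, design wants {design.n_genotypes}"
        )
    tp = np.asarray(design.time_points, dtype=float)
    if tp.min() < 0 or tp.max() > 200:
        logger.warning("time points outside [0, 200] DAP")
    rows = []
    for g in genotypes:
        theta = theta_by_genotype[g]
        if not isinstance(theta, GrowthParams):
            theta = GrowthParams(*theta)
        f = growth_curve(tp, theta, decay_mode)
        peak = max(float(np.max(f)), 1e-9)
        for p in range(1, design.n_plants + 1):
            for rep in range(1, design.n_replicates + 1):
                sd = sigma_obs * (0.5 + f / peak) if heteroscedastic else sigma_obs
                y = f + rng.normal(0.0, 1.0, size=len(tp)) * sd
                for j, t in enumerate(tp):
                    rows.append(
                        {"genotype_id": g, "plant_id": f"{g}_p{p:02d}",
                         "replicate_id": rep, "t": float(t), "y": float(y[j])}
                    )
    df = pd.DataFrame(rows)
    assert len(df) == design.n_records
    return df


# --------------------------------------------------------------------------
# direct feature-table simulation for the regression stage
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureNoiseConfig:
    """View-specific degradation of the true canopy descriptors: single views
    carry more occlusion-driven height shrinkage and feature noise than the
    combined reconstruction."""

    height_shrink: dict = field(
        default_factory=lambda: {"OBLIQUE60": 0.12, "NADIR90": 0.22, "COMBINED": 0.04}
    )
    feature_noise: dict = field(
        default_factory=lambda: {"OBLIQUE60": 0.10, "NADIR90": 0.15, "COMBINED": 0.05}
    )


def simulate_feature_dataset(
    design: FieldDesign = FieldDesign(),
    seed: int = 0,
    noise: FeatureNoiseConfig | None = None,
    biomass_noise_sd: float = 12.0,
):
    """Feature tables + destructive biomass for the regression stage.

    For every destructively sampled plant of the field design, a latent
    biomass (genotype x treatment x stage effects, lognormal spread) drives
    true canopy geometry; per-view features are the true descriptors degraded
    by the view's occlusion noise. Returns ``(features, biomass)`` frames:
    features with one row per plant per view, biomass with the measured shoot
    dry weight per plant.
    """
    noise = noise or FeatureNoiseConfig()
    rng = np.random.default_rng(seed)
    tables = simulate_field_design(design, seed=seed)
    sampling = tables.sampling
    genotypes = sorted(sampling["genotype_id"].unique())
    g_effect = dict(zip(genotypes, rng.lognormal(0.0, 0.25, size=len(genotypes))))
    stage_mean = {dap: 30.0 + 1.1 * dap for dap in sorted(set(sampling["dap"]))}
    year_effect = {y: e for y, e in zip(
        sorted(sampling["year"].unique()),
        rng.lognormal(0.0, 0.08, size=sampling["year"].nunique()),
    )}

    feat_rows, bio_rows = [], []
    for _, rec in sampling.iterrows():
        tr_mult = 1.35 if rec["treatment"] == "fertilized" else 1.0
        mean_b = stage_mean[rec["dap"]] * g_effect[rec["genotype_id"]] * tr_mult
        mean_b *= year_effect[rec["year"]]
        b = mean_b * rng.lognormal(0.0, 0.30)
        measured = max(b + rng.normal(0.0, biomass_noise_sd), 0.0)
        # true canopy descriptors: saturating area, power-law height
        height = 0.28 * b**0.42
        radius = min(0.18 * b**0.28, 0.5)
        cover = 1.0 - math.exp(-b / 60.0)
        a_proj_true = min(math.pi * radius**2 * cover, 1.0)
        greenness = 0.30 * (1.0 - math.exp(-b / 80.0))
        bio_rows.append(
            {"plant_id": rec["plant_id"], "genotype_id": rec["genotype_id"],
             "treatment": rec["treatment"], "year": rec["year"], "dap": rec["dap"],
             "shoot_dry_weight_g": measured}
        )
        for view in ("OBLIQUE60", "NADIR90", "COMBINED"):
            shrink = noise.height_shrink[view]
            eps = noise.feature_noise[view]
            h_obs = height * (1.0 - shrink * rng.uniform(0.5, 1.5))
            h_ave = max(h_obs * rng.uniform(0.55, 0.75), 0.0)
            h_max = max(h_obs, h_ave)
            a_obs = float(np.clip(a_proj_true * (1.0 - 0.5 * shrink) * (1 + eps * rng.normal()), 0.0, 1.0))
            base = greenness * (1 + eps * rng.normal())
            feat_rows.append(
                {"plant_id": rec["plant_id"], "view": view,
                 "A_proj": a_obs,
                 "GRVI": float(np.clip(base + 0.02 * rng.normal(), -1, 1)),
                 "GLI": float(np.clip(0.9 * base + 0.02 * rng.normal(), -1, 1)),
                 "VARI": float(np.clip(1.2 * base + 0.03 * rng.normal(), -1, 1)),
                 "GSI": float(np.clip(0.8 * base + 0.02 * rng.normal(), -1, 1)),
                 "H_max": h_max, "H_ave": h_ave,
                 "genotype_id": rec["genotype_id"], "treatment": rec["treatment"],
                 "year": rec["year"], "dap": rec["dap"]}
            )
    return pd.DataFrame(feat_rows), pd.DataFrame(bio_rows)


# --------------------------------------------------------------------------
# linking growth state to renderable patches
# --------------------------------------------------------------------------


def state_from_biomass(
    plant_id: str,
    genotype_id: str,
    biomass: float,
    dap: float = 60.0,
    treatment: str = "unfertilized",
    year: int = 1,
    architecture: float = 0.7,
) -> PlantState:
    """Map a latent biomass to plausible canopy geometry (monotone in biomass)."""
    b = max(float(biomass), 0.0)
    return PlantState(
        plant_id=plant_id, genotype_id=genotype_id, treatment=treatment, year=year,
        dap=dap, latent_biomass=b,
        canopy_height=0.28 * b**0.42,
        canopy_radius=min(0.18 * b**0.28, 0.5),
        architecture=architecture,
        leaf_cover=1.0 - math.exp(-b / 60.0) if b > 0 else 0.0,
    )
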