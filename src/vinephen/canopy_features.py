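"""Per-plant canopy feature extraction from co-registered RGB + DEM patches.

Seven explanatory variables are extracted per plant and view set: projected
canopy area (A_proj, m^2), four RGB vegetation indices (GRVI, GLI, VARI and
the grayscale-contrast index GSI with a tunable weight ``a``), and two height
metrics (H_max, H_ave, m) measured against the local ground elevation.

Index formulas (reflectances R, G, B in [0, 1]):

    GRVI = (G - R) / (G + R)
    GLI  = (2G - R - B) / (2G + R + B)
    VARI = (G - R) / (G + R - B)
    GSI  = (G - gray) / (G + gray),   gray = a R + (1 - a) B

GSI's weight can be optimized over a grid by maximizing the Pearson
correlation between per-patch GSI and A_proj across a patch collection.

Rasters live on a local metric grid, row-major with the origin at the top
left; the plant polygon shares that frame and pixel membership is decided by
the pixel center (half-open convention). Per-plant index values are the mean
over vegetation-mask pixels; pixels whose index denominator is within 1e-9 of
zero are excluded from that index's mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon, mapping, shape
from skimage.filters import threshold_otsu

logger = logging.getLogger("vinephen.canopy_features")

VIEWS = ("OBLIQUE60", "NADIR90", "COMBINED")
INDEX_NAMES = ("GRVI", "GLI", "VARI", "GSI")
FEATURE_COLUMNS = ("A_proj", "GRVI", "GLI", "VARI", "GSI", "H_max", "H_ave")

_DENOM_EPS = 1e-9


class DegenerateThresholdError(ValueError):
    """Auto-thresholding failed because the image has no contrast."""


class UndefinedCorrelationError(ValueError):
    """GSI weight optimization with a degenerate (constant) target."""


class DuplicateRecordError(ValueError):
    """Two patches claim the same (plant, view) slot."""


@dataclass(frozen=True)
class GsiConfig:
    """GSI weighting coefficient, its optimization grid, and the optimize flag.

    The default a = 0.635 is the reference weight; the default grid spans
    [0, 1] in steps of 0.005 so that 0.635 is an exact grid point.
    """

    a: float = 0.635
    a_grid: tuple = tuple(np.round(np.arange(0.0, 1.0001, 0.005), 3))
    optimize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("GSI weight a must lie in [0, 1]")
        grid = np.asarray(self.a_grid, dtype=float)
        if len(grid) == 0 or np.any(grid < 0) or np.any(grid > 1):
            raise ValueError("a_grid must be a nonempty subset of [0, 1]")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("a_grid must be sorted strictly increasing")


@dataclass
class PlantPatch:
    """Co-registered RGB reflectance + DEM rasters with the plant polygon.

    ``rgb``: (H, W, 3) float reflectance in [0, 1]; ``dem``: (H, W) float
    elevation in metres; ``polygon``: the 1 x 1 m extraction square in patch
    coordinates (metres, x right / y down from the top-left raster corner).
    """

    rgb: np.ndarray
    dem: np.ndarray
    polygon: Polygon
    pixel_size_m: float
    view: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        self.dem = np.asarray(self.dem, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if self.dem.shape != self.rgb.shape[:2]:
            raise ValueError("rgb and dem must share the same grid")
        if not self.pixel_size_m > 0:
            raise ValueError("pixel_size_m must be positive")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        h, w = self.dem.shape
        minx, miny, maxx, maxy = self.polygon.bounds
        if minx < 0 or miny < 0 or maxx > w * self.pixel_size_m or maxy > h * self.pixel_size_m:
            raise ValueError("polygon extends outside the raster")

    @property
    def shape(self):
        return self.dem.shape

    def pixel_centers(self):
        """(X, Y) metric coordinates of all pixel centers."""
        h, w = self.dem.shape
        x = (np.arange(w) + 0.5) * self.pixel_size_m
        y = (np.arange(h) + 0.5) * self.pixel_size_m
        return np.meshgrid(x, y)

    def polygon_mask(self) -> np.ndarray:
        """Boolean raster of pixels whose centers fall inside the polygon."""
        X, Y = self.pixel_centers()
        return shapely.contains_xy(self.polygon, X.ravel(), Y.ravel()).reshape(self.dem.shape)


@dataclass(frozen=True)
class FeatureVector:
    """The seven explanatory variables for one plant and view set."""

    A_proj: float
    GRVI: float
    GLI: float
    VARI: float
    GSI: float
    H_max: float
    H_ave: float
    view: str
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in FEATURE_COLUMNS}
        out["view"] = self.view
        out.update(self.metadata)
        return out


# --------------------------------------------------------------------------
# masking and per-patch metrics
# --------------------------------------------------------------------------


def _per_pixel_index(rgb: np.ndarray, which: str, a: float = 0.635):
    """Per-pixel index values and a validity mask (denominator guard)."""
    R, G, B = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    if which == "GRVI":
        num, den = G - R, G + R
    elif which == "GLI":
        num, den = 2 * G - R - B, 2 * G + R + B
    elif which == "VARI":
        num, den = G - R, G + R - B
    elif which == "GSI":
        gray = a * R + (1 - a) * B
        num, den = G - gray, G + gray
    else:
        raise ValueError(f"unknown index {which!r}")
    valid = np.abs(den) >= _DENOM_EPS
    vals = np.zeros_like(num)
    np.divide(num, den, out=vals, where=valid)
    return vals, valid


def vegetation_mask(
    rgb: np.ndarray,
    method: str = "gli_otsu",
    threshold: float | None = None,
    min_threshold: float = 0.2,
):
    """Binary vegetation mask from RGB reflectance.

    ``"gli_otsu"`` thresholds the per-pixel GLI image with Otsu's method (a
    reproducible stand-in for interactive thresholding), floored at
    ``min_threshold`` so vegetation-free patches do not split their soil
    noise; ``"gli_fixed"`` uses the supplied ``threshold``. Raises
    :class:`DegenerateThresholdError` when auto-thresholding is asked for a
    contrast-free image.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("reflectance must lie in [0, 1]")
    gli, valid = _per_pixel_index(rgb, "GLI")
    if method == "gli_fixed":
        if threshold is None:
            raise ValueError("gli_fixed needs an explicit threshold")
        thr = threshold
    elif method == "gli_otsu":
        vals = gli[valid]
        if vals.size == 0 or np.ptp(vals) == 0.0:
            raise DegenerateThresholdError("constant image: Otsu threshold undefined")
        thr = max(threshold_otsu(vals), min_threshold)
    else:
        raise ValueError(f"unknown masking method {method!r}")
    return (gli > thr) & valid


def projected_area(mask: np.ndarray, polygon: Polygon, pixel_size_m: float) -> float:
    """Projected canopy area: vegetation pixels inside the polygon x pixel area."""
    h, w = mask.shape
    x = (np.arange(w) + 0.5) * pixel_size_m
    y = (np.arange(h) + 0.5) * pixel_size_m
    X, Y = np.meshgrid(x, y)
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(mask.shape)
    return float(np.count_nonzero(mask & inside)) * pixel_size_m**2


def vegetation_index(
    rgb: np.ndarray, mask: np.ndarray, which: str, gsi: GsiConfig | None = None
) -> float:
    """Mean per-pixel index over the vegetation mask (NaN on an empty mask)."""
    a = (gsi or GsiConfig()).a
    vals, valid = _per_pixel_index(np.asarray(rgb, dtype=float), which, a=a)
    sel = np.asarray(mask, dtype=bool) & valid
    if not sel.any():
        logger.warning("empty vegetation mask: %s undefined", which)
        return float("nan")
    return float(vals[sel].mean())


def height_metrics(
    dem: np.ndarray,
    polygon: Polygon,
    mask: np.ndarray,
    pixel_size_m: float,
    ground_percentile: float = 5.0,
):
    """(H_max, H_ave) against the local ground elevation.

    Ground is the ``ground_percentile``-th percentile of the in-polygon DEM;
    per-pixel heights are DEM minus ground clipped at zero, and the metrics
    are taken over vegetation pixels inside the polygon.
    """
    dem = np.asarray(dem, dtype=float)
    h, w = dem.shape
    x = (np.arange(w) + 0.5) * pixel_size_m
    y = (np.arange(h) + 0.5) * pixel_size_m
    X, Y = np.meshgrid(x, y)
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(dem.shape)
    if not np.isfinite(dem[inside]).all():
        raise ValueError("DEM contains non-finite values inside the polygon")
    ground = np.percentile(dem[inside], ground_percentile)
    heights = np.clip(dem - ground, 0.0, None)
    sel = inside & np.asarray(mask, dtype=bool)
    if not sel.any():
        logger.warning("empty vegetation mask: height metrics undefined")
        return float("nan"), float("nan")
    return float(heights[sel].max()), float(heights[sel].mean())


def gsi_weight_optimize(patches, a_grid=None, mask_method: str = "gli_otsu"):
    """Grid-search the GSI weight maximizing Pearson r(GSI, A_proj).

    Each patch contributes one (mean GSI(a), A_proj) pair; returns the grid
    argmax, ties broken toward the smaller weight. Needs at least three
    patches and a non-constant A_proj.
    """
    grid = np.asarray(a_grid if a_grid is not None else GsiConfig().a_grid, dtype=float)
    patches = list(patches)
    if len(patches) < 3:
        raise ValueError("GSI weight optimization needs at least 3 patches")
    a_proj = np.empty(len(patches))
    gsi_mat = np.empty((len(patches), len(grid)))
    for i, patch in enumerate(patches):
        mask = vegetation_mask(patch.rgb, method=mask_method)
        a_proj[i] = projected_area(mask, patch.polygon, patch.pixel_size_m)
        for j, a in enumerate(grid):
            gsi_mat[i, j] = vegetation_index(patch.rgb, mask, "GSI", GsiConfig(a=a))
    if np.ptp(a_proj) == 0.0:
        raise UndefinedCorrelationError("A_proj is constant across the collection")
    corrs = np.full(len(grid), -np.inf)
    for j in range(len(grid)):
        col = gsi_mat[:, j]
        if not np.isfinite(col).all() or np.ptp(col) == 0.0:
            continue
        corrs[j] = float(np.corrcoef(col, a_proj)[0, 1])
    if not np.isfinite(corrs).any():
        raise UndefinedCorrelationError("no grid point yields a finite correlation")
    best = int(np.argmax(corrs))  # argmax returns the first (smallest a) on ties
    return float(grid[best]), pd.DataFrame({"a": grid, "pearson_r": corrs})


# --------------------------------------------------------------------------
# per-patch and tabular extraction
# --------------------------------------------------------------------------


def extract_features(
    patch: PlantPatch,
    gsi: GsiConfig | None = None,
    mask_method: str = "gli_otsu",
    ground_percentile: float = 5.0,
) -> FeatureVector:
    """All seven variables for a single patch (pure: depends on it alone)."""
    gsi = gsi or GsiConfig()
    try:
        mask = vegetation_mask(patch.rgb, method=mask_method)
    except DegenerateThresholdError:
        # contrast-free patch (e.g. bare soil): no vegetation
        mask = np.zeros(patch.shape, dtype=bool)
    area = projected_area(mask, patch.polygon, patch.pixel_size_m)
    idx = {
        name: vegetation_index(patch.rgb, mask, name, gsi) for name in INDEX_NAMES
    }
    h_max, h_ave = height_metrics(
        patch.dem, patch.polygon, mask, patch.pixel_size_m, ground_percentile
    )
    return FeatureVector(
        A_proj=area, GRVI=idx["GRVI"], GLI=idx["GLI"], VARI=idx["VARI"], GSI=idx["GSI"],
        H_max=h_max, H_ave=h_ave, view=patch.view, metadata=dict(patch.metadata),
    )


def build_feature_table(
    patches,
    views=VIEWS,
    gsi: GsiConfig | None = None,
    mask_method: str = "gli_otsu",
    ground_percentile: float = 5.0,
) -> pd.DataFrame:
    """One row per plant per requested view set.

    Patches are keyed by ``metadata["plant_id"]`` and their view. A COMBINED
    row always comes from the COMBINED patch itself, never from averaging the
    single views. Missing (plant, view) slots yield rows with NaN features and
    ``missing = True``; duplicates raise :class:`DuplicateRecordError`.
    """
    gsi = gsi or GsiConfig()
    if gsi.optimize:
        patches = list(patches)
        a_star, _ = gsi_weight_optimize(patches, gsi.a_grid, mask_method)
        gsi = GsiConfig(a=a_star, a_grid=gsi.a_grid, optimize=False)
        logger.info("GSI weight optimized to a = %.3f", a_star)
    by_key: dict = {}
    for patch in patches:
        pid = patch.metadata.get("plant_id")
        if pid is None:
            raise ValueError("every patch needs metadata['plant_id']")
        key = (pid, patch.view)
        if key in by_key:
            raise DuplicateRecordError(f"duplicate patch for plant {pid!r}, view {patch.view}")
        by_key[key] = patch
    plant_ids = sorted({pid for pid, _ in by_key})
    rows = []
    n_missing = 0
    for pid in plant_ids:
        for view in views:
            patch = by_key.get((pid, view))
            if patch is None:
                n_missing += 1
                rows.append(
                    {"plant_id": pid, "view": view, "missing": True,
                     **{c: float("nan") for c in FEATURE_COLUMNS}}
                )
                continue
            fv = extract_features(patch, gsi, mask_method, ground_percentile)
            row = fv.as_dict()
            row.update(plant_id=pid, missing=False)
            rows.append(row)
    if n_missing:
        logger.warning("%d missing (plant, view) patches flagged in the table", n_missing)
    df = pd.DataFrame(rows)
    lead = ["plant_id", "view", "missing", *FEATURE_COLUMNS]
    return df[lead + [c for c in df.columns if c not in lead]]


# --------------------------------------------------------------------------
# patch I/O (TIFF rasters + GeoJSON polygon + JSON metadata sidecar)
# --------------------------------------------------------------------------


def save_patch(patch: PlantPatch, directory, stem: str) -> dict:
    """Write ``<stem>_rgb.tif``, ``<stem>_dem.tif``, ``<stem>.geojson`` and
    ``<stem>_meta.json`` under ``directory``; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "rgb": directory / f"{stem}_rgb.tif",
        "dem": directory / f"{stem}_dem.tif",
        "polygon": directory / f"{stem}.geojson",
        "meta": directory / f"{stem}_meta.json",
    }
    tifffile.imwrite(paths["rgb"], patch.rgb.astype(np.float32))
    tifffile.imwrite(paths["dem"], patch.dem.astype(np.float32))
    feature = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(patch.polygon)}
        ],
    }
    paths["polygon"].write_text(json.dumps(feature))
    meta = {"pixel_size_m": patch.pixel_size_m, "view": patch.view, "metadata": patch.metadata}
    paths["meta"].write_text(json.dumps(meta, default=str))
    return {k: str(v) for k, v in paths.items()}


def load_patch(directory, stem: str) -> PlantPatch:
    directory = Path(directory)
    rgb = np.asarray(tifffile.imread(directory / f"{stem}_rgb.tif"), dtype=float)
    dem = np.asarray(tifffile.imread(directory / f"{stem}_dem.tif"), dtype=float)
    geo = json.loads((directory / f"{stem}.geojson").read_text())
    polygon = shape(geo["features"][0]["geometry"])
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    return PlantPatch(
        rgb=rgb, dem=dem, polygon=polygon,
        pixel_size_m=meta["pixel_size_m"], view=meta["view"], metadata=meta["metadata"],
    )
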