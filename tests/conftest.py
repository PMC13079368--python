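import numpy as np
import pytest

from vinephen.growth_bayes import GrowthParams
from vinephen.synthcanopy import (
    PatchRenderConfig, PlantState, SeriesDesign, draw_genotype_params,
    simulate_canopy_patch, simulate_growth_series,
)


@pytest.fixture(scope="session")
def theta_small():
    """Three genotypes drawn from the default population."""
    return draw_genotype_params(n_genotypes=3, seed=101)


@pytest.fixture(scope="session")
def small_series(theta_small):
    """3 genotypes x 2 plants x 1 replicate x 11 time points, moderate noise."""
    design = SeriesDesign(n_genotypes=3, n_plants=2, n_replicates=1)
    return simulate_growth_series(theta_small, sigma_obs=10.0, design=design, seed=102)


@pytest.fixture
def reference_theta():
    return GrowthParams(A=150.0, nu=2.0, k=0.08, t_i=100.0, d=0.02, t_d=190.0)


@pytest.fixture
def unbiased_render():
    """Rendering config with no view-dependent height bias or dropout."""
    return PatchRenderConfig(
        view_bias_m={v: 0.0 for v in ("OBLIQUE60", "NADIR90", "COMBINED")},
        view_dropout={v: 0.0 for v in ("OBLIQUE60", "NADIR90", "COMBINED")},
        dem_noise_sd=0.0,
    )


@pytest.fixture
def cylinder_state():
    """Full-cover cylindrical canopy of height 2.0 m."""
    return PlantState(
        plant_id="p1", genotype_id="g01", latent_biomass=120.0,
        canopy_height=2.0, canopy_radius=0.40, architecture=1.0, leaf_cover=1.0,
    )


@pytest.fixture
def seeded_patches():
    """50 varied seeded patches for oracle-equivalence checks."""
    rng = np.random.default_rng(2024)
    patches = []
    for i in range(50):
        b = float(rng.uniform(5.0, 250.0))
        state = PlantState(
            plant_id=f"p{i:02d}", genotype_id=f"g{i % 5:02d}",
            latent_biomass=b,
            canopy_height=float(rng.uniform(0.3, 2.5)),
            canopy_radius=float(rng.uniform(0.1, 0.5)),
            architecture=float(rng.uniform(0.0, 1.0)),
            leaf_cover=float(rng.uniform(0.4, 1.0)),
        )
        view = ("OBLIQUE60", "NADIR90", "COMBINED")[i % 3]
        patches.append(simulate_canopy_patch(state, view, pixel_size_m=0.02, seed=3000 + i))
    return patches
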