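import numpy as np
import pandas as pd
import pytest

import uavbiomass as ub
from uavbiomass.features import VI_REGISTRY
from uavbiomass.synthetic_field import _canopy_bands

#: the eleven indices named in the modeling narrative (no fill-ins)
NAMED_VIS = (
    "ndvi", "ndre", "ngrdi", "sr", "ci_rededge", "ci_green", "grvi",
    "evi", "rvi", "mcari", "exg",
)

MODEL_FEATURES = ("area", "height", "ngrdi", "ndre")


@pytest.fixture(scope="session")
def small_layout() -> ub.FieldLayout:
    """One replicate, 4 x 3 plots, one blank — a desk-sized field."""
    return ub.FieldLayout(replicates=1, rows=4, cols=3, blanks=((0, 1, 1),))


@pytest.fixture(scope="session")
def may() -> ub.MonthPreset:
    return ub.MONTH_PRESETS["May"]


@pytest.fixture(scope="session")
def truth_small(small_layout, may) -> pd.DataFrame:
    return ub.simulate_plot_truth(small_layout, may, noise_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def rendered_small(truth_small, small_layout):
    """Noiseless rendered small field plus its plot map."""
    return ub.render_field_raster(truth_small, small_layout, pixel_noise_sd=0.0)


@pytest.fixture(scope="session")
def segments_small(rendered_small):
    raster, plot_map = rendered_small
    classes = ub.cluster_pixels(raster, k=2, seed=0)
    veg = ub.select_vegetation_class(classes, raster)
    grid = ub.detect_plot_grid(veg, expected=(4, 3))
    return veg, grid, ub.refine_plot_boundaries(veg, grid, plot_map)


@pytest.fixture(scope="session")
def field_std_table() -> pd.DataFrame:
    """Default 808-plot field over three months, standardized scale (n=2424)."""
    truth = ub.simulate_field(ub.FieldLayout(), seed=11)
    return ub.truth_to_model_table(truth, scale="standardized")


def make_vi_feature_table(seed: int = 11) -> pd.DataFrame:
    """Full-size 22-feature natural-unit table: area/height/volume from truth,
    the named VIs recomputed from per-plot band means implied by the truth."""
    truth = ub.simulate_field(ub.FieldLayout(), seed=seed)
    nat = ub.truth_to_model_table(truth, scale="natural")
    bands: dict[str, list] = {k: [] for k in ("blue", "green", "red", "red_edge", "nir")}
    for rec in truth.itertuples():
        b = _canopy_bands(rec.ndvi, rec.ndre, rec.ngrdi, 0.35, 0.05)
        for k, v in b.items():
            bands[k].append(v)
    bm = {k: np.asarray(v) for k, v in bands.items()}
    table = nat[["month", "replicate", "row", "col", "area", "height", "volume", "biomass"]].copy()
    for name in NAMED_VIS:
        table[name] = VI_REGISTRY[name](bm)
    return table


@pytest.fixture(scope="session")
def vi_feature_table() -> pd.DataFrame:
    return make_vi_feature_table(seed=11)
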