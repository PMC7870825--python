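"""Synthetic alfalfa field: plot-level ground truth and rendered rasters.

The generator reproduces the statistical structure of the study field so the
whole pipeline is testable without field data:

* layout — 3 replicates x 23 rows x 12 columns of 1.52 m x 0.30 m plots,
  0.91 m row gap, 0.30 m column gap, imaged at 0.98 cm/pixel. The default
  blank positions leave 269/269/270 sown plots per replicate (808 total).
* per-month presets — plot-mean biomass, vegetative area, canopy height,
  NDVI, NDRE and NGRDI moments for the May, July and September harvests.
* generative model — each plot draws a latent vigor v ~ N(0,1); the
  standardized features load on v (area = v; height, NGRDI, NDRE, NDVI with
  configurable loadings bracketing the observed 0.3-0.7 inter-feature
  correlations); standardized biomass is the four-feature linear combination
  0.70*area + 0.07*height + 0.18*NGRDI + 0.07*NDRE plus Gaussian noise.
  Features and biomass are then de-standardized to the month preset moments
  (biomass truncated at 0 kg).

Rendering paints each sown plot as a centred rectangle-with-eroded-corners
(a superellipse) whose canopy pixel count matches the plot's true vegetative
area, with per-plot canopy reflectances solved so the canopy-mean NDVI/NDRE/
NGRDI equal the truth values; soil pixels get a fixed soil reflectance.
The canopy-height layer carries the true height on canopy pixels, 0
elsewhere. No radiative transfer or shadow simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import MultibandFieldRaster, PlotMap

#: final four-feature prediction coefficients, order (area, height, NGRDI, NDRE)
EQ1_BETA = (0.70, 0.07, 0.18, 0.07)
#: full-training-data variant of the same model (no outlier group removed)
FULL_BETA = (0.66, 0.07, 0.15, 0.04)

BETA_ORDER = ("area", "height", "ngrdi", "ndre")

#: default loadings of each standardized feature on the latent plot vigor
DEFAULT_LOADINGS = {"height": 0.5, "ngrdi": 0.6, "ndre": 0.3, "ndvi": 0.6}

#: soil reflectance per band; soil NDVI ~ 0.29, below spring/summer canopy
SOIL_REFLECTANCE = {
    "blue": 0.06, "green": 0.10, "red": 0.12, "red_edge": 0.18, "nir": 0.22,
}

# blank (never-sown) positions of the default 3 x 23 x 12 layout: 7/7/6 per
# replicate so the sown counts are 269/269/270 (808 plots)
_DEFAULT_BLANKS = (
    (0, 1, 5), (0, 4, 9), (0, 7, 2), (0, 10, 7), (0, 13, 11), (0, 17, 4), (0, 21, 8),
    (1, 2, 3), (1, 5, 10), (1, 9, 6), (1, 12, 1), (1, 16, 9), (1, 19, 5), (1, 22, 11),
    (2, 3, 8), (2, 8, 0), (2, 11, 10), (2, 15, 6), (2, 18, 11), (2, 20, 2),
)


@dataclass(frozen=True)
class FieldLayout:
    """Geometry of the plot grid and of the rendered raster."""

    replicates: int = 3
    rows: int = 23
    cols: int = 12
    plot_length_m: float = 1.52
    plot_width_m: float = 0.30
    row_gap_m: float = 0.91
    col_gap_m: float = 0.30
    gsd_cm: float = 0.98
    blanks: tuple[tuple[int, int, int], ...] | None = None
    margin_m: float = 0.5
    replicate_gap_m: float = 2.0

    def __post_init__(self) -> None:
        for name in ("replicates", "rows", "cols"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("plot_length_m", "plot_width_m", "gsd_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.blanks is None:
            default = tuple(
                b for b in _DEFAULT_BLANKS
                if b[0] < self.replicates and b[1] < self.rows and b[2] < self.cols
            )
            object.__setattr__(self, "blanks", default)

    # -- pixel geometry -----------------------------------------------------

    def _px(self, metres: float) -> int:
        return int(round(metres * 100.0 / self.gsd_cm))

    @property
    def plot_shape_px(self) -> tuple[int, int]:
        """Plot rectangle (rows, cols) in pixels: width across rows, length across cols."""
        return (self._px(self.plot_width_m), self._px(self.plot_length_m))

    @property
    def plot_px(self) -> int:
        h, w = self.plot_shape_px
        return h * w

    @property
    def pitch_px(self) -> tuple[int, int]:
        return (
            self._px(self.plot_width_m + self.row_gap_m),
            self._px(self.plot_length_m + self.col_gap_m),
        )

    @property
    def raster_shape(self) -> tuple[int, int]:
        pr, pc = self.pitch_px
        m = self._px(self.margin_m)
        H = 2 * m + self.replicates * self.rows * pr
        H += (self.replicates - 1) * self._px(self.replicate_gap_m)
        W = 2 * m + self.cols * pc
        return (H, W)

    def cell_box(self, rep: int, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open (r0, r1, c0, c1) pixel box of one grid cell."""
        pr, pc = self.pitch_px
        m = self._px(self.margin_m)
        r0 = m + rep * (self.rows * pr + self._px(self.replicate_gap_m)) + row * pr
        c0 = m + col * pc
        return (r0, r0 + pr, c0, c0 + pc)

    def plot_box(self, rep: int, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open pixel box of the sown plot rectangle, centred in its cell."""
        r0, r1, c0, c1 = self.cell_box(rep, row, col)
        ph, pw = self.plot_shape_px
        dr = (r1 - r0 - ph) // 2
        dc = (c1 - c0 - pw) // 2
        return (r0 + dr, r0 + dr + ph, c0 + dc, c0 + dc + pw)

    def positions(self):
        """Yield (replicate, row, col, blank) over the whole design."""
        blanks = set(self.blanks)
        for rep in range(self.replicates):
            for row in range(self.rows):
                for col in range(self.cols):
                    yield rep, row, col, (rep, row, col) in blanks


@dataclass(frozen=True)
class MonthPreset:
    """Per-month plot-level moments (natural units: kg, pixels, cm, unitless VIs)."""

    month: str
    biomass_mean: float
    biomass_sd: float
    area_mean: float
    area_sd: float
    height_mean: float
    height_sd: float
    ndvi_mean: float
    ndvi_sd: float
    ndre_mean: float
    ndre_sd: float
    ngrdi_mean: float
    ngrdi_sd: float

    def __post_init__(self) -> None:
        for name in ("biomass_sd", "area_sd", "height_sd", "ndvi_sd", "ndre_sd", "ngrdi_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


#: May / July / September presets: replicate-averaged field moments
MONTH_PRESETS: dict[str, MonthPreset] = {
    "May": MonthPreset(
        "May", biomass_mean=3.88333, biomass_sd=0.58333,
        area_mean=4497.67, area_sd=579.67, height_mean=33.83, height_sd=6.32,
        ndvi_mean=0.39233, ndvi_sd=0.05117, ndre_mean=-0.40787, ndre_sd=0.00493,
        ngrdi_mean=0.28280, ngrdi_sd=0.01160,
    ),
    "July": MonthPreset(
        "July", biomass_mean=2.29667, biomass_sd=0.80667,
        area_mean=3613.00, area_sd=578.00, height_mean=38.81667, height_sd=6.02,
        ndvi_mean=0.40290, ndvi_sd=0.03683, ndre_mean=-0.40883, ndre_sd=0.00460,
        ngrdi_mean=0.24063, ngrdi_sd=0.01613,
    ),
    "September": MonthPreset(
        "September", biomass_mean=0.37, biomass_sd=0.20333,
        area_mean=1616.00, area_sd=419.33, height_mean=19.36, height_sd=6.09667,
        ndvi_mean=0.27557, ndvi_sd=0.04783, ndre_mean=-0.41317, ndre_sd=0.00517,
        ngrdi_mean=0.14637, ngrdi_sd=0.01950,
    ),
}


def _loading_matrix(loadings: dict[str, float]) -> np.ndarray:
    """Feature correlation matrix implied by the single-factor loadings.

    Order (area, height, ngrdi, ndre); area loads 1 on the vigor factor.
    """
    lam = np.array([1.0, loadings["height"], loadings["ngrdi"], loadings["ndre"]])
    sigma = np.outer(lam, lam)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def generative_r2(
    beta=EQ1_BETA, noise_sd: float = 0.55, loadings: dict[str, float] | None = None
) -> float:
    """R-squared implied by the generative model: signal var / total var."""
    loadings = loadings or DEFAULT_LOADINGS
    b = np.asarray(beta, dtype=float)
    signal = float(b @ _loading_matrix(loadings) @ b)
    return signal / (signal + noise_sd**2)


def noise_sd_for_r2(
    r2: float, beta=EQ1_BETA, loadings: dict[str, float] | None = None
) -> float:
    """Noise sd that makes the generative R-squared equal ``r2``."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    loadings = loadings or DEFAULT_LOADINGS
    b = np.asarray(beta, dtype=float)
    signal = float(b @ _loading_matrix(loadings) @ b)
    return float(np.sqrt(signal * (1.0 - r2) / r2))


def simulate_plot_truth(
    layout: FieldLayout,
    preset: MonthPreset,
    beta=EQ1_BETA,
    noise_sd: float = 0.55,
    seed: int = 0,
    loadings: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw per-plot ground truth for one month.

    Returns one row per sown (non-blank) plot with both the generative
    standardized columns (``*_std``, ``biomass_std``) and the de-standardized
    natural-unit columns (``area_px``, ``area_frac``, ``height_cm``, VI
    values, ``biomass_kg``). ``biomass_kg`` is truncated at 0; ``area_px`` is
    clipped to the plot-rectangle capacity so ``area_frac`` stays in (0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(beta) != 4:
        raise ValueError("beta must have length 4: (area, height, ngrdi, ndre)")
    loadings = loadings or DEFAULT_LOADINGS
    rng = np.random.default_rng(seed)
    pos = [(r, i, j) for r, i, j, blank in layout.positions() if not blank]
    n = len(pos)

    vigor = rng.standard_normal(n)

    def load(name: str) -> np.ndarray:
        rho = loadings[name]
        return rho * vigor + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    std = {
        "area": vigor.copy(),
        "height": load("height"),
        "ngrdi": load("ngrdi"),
        "ndre": load("ndre"),
        "ndvi": load("ndvi"),
    }
    b = np.asarray(beta, dtype=float)
    biomass_std = (
        b[0] * std["area"] + b[1] * std["height"]
        + b[2] * std["ngrdi"] + b[3] * std["ndre"]
        + rng.normal(0.0, noise_sd, n)
    )

    cap = layout.plot_px
    area_px = np.clip(
        np.rint(preset.area_mean + preset.area_sd * std["area"]), 16, cap
    ).astype(int)
    df = pd.DataFrame(pos, columns=["replicate", "row", "col"])
    df.insert(0, "month", preset.month)
    df["vigor"] = vigor
    for name in ("area", "height", "ngrdi", "ndre", "ndvi"):
        df[f"{name}_std"] = std[name]
    df["biomass_std"] = biomass_std
    df["area_px"] = area_px
    df["area_frac"] = area_px / cap
    df["height_cm"] = np.clip(preset.height_mean + preset.height_sd * std["height"], 0.5, None)
    df["ndvi"] = np.clip(preset.ndvi_mean + preset.ndvi_sd * std["ndvi"], 0.01, 0.95)
    df["ndre"] = np.clip(preset.ndre_mean + preset.ndre_sd * std["ndre"], -0.95, 0.95)
    df["ngrdi"] = np.clip(preset.ngrdi_mean + preset.ngrdi_sd * std["ngrdi"], -0.95, 0.95)
    df["biomass_kg"] = np.clip(preset.biomass_mean + preset.biomass_sd * biomass_std, 0.0, None)
    return df


def simulate_field(
    layout: FieldLayout,
    months: tuple[str, ...] = ("May", "July", "September"),
    beta=EQ1_BETA,
    noise_sd: float = 0.55,
    seed: int = 0,
    loadings: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Stack per-month truths (independent month draws from one seed stream)."""
    seeds = np.random.SeedSequence(seed).generate_state(len(months)) % (2**31)
    frames = [
        simulate_plot_truth(
            layout, MONTH_PRESETS[m], beta=beta, noise_sd=noise_sd,
            seed=int(s), loadings=loadings,
        )
        for m, s in zip(months, seeds)
    ]
    return pd.concat(frames, ignore_index=True)


def truth_to_model_table(truth: pd.DataFrame, scale: str = "standardized") -> pd.DataFrame:
    """Reshape a truth table into the modeling layout.

    ``scale="standardized"`` exposes the generative standardized columns as
    ``area/height/ngrdi/ndre`` plus ``biomass``; ``scale="natural"`` exposes
    the de-standardized units (pixels, cm, unitless VIs, kg) plus
    ``volume = area * height``.
    """
    keys = truth[["month", "replicate", "row", "col"]].copy()
    if scale == "standardized":
        vals = pd.DataFrame({
            "area": truth["area_std"], "height": truth["height_std"],
            "ngrdi": truth["ngrdi_std"], "ndre": truth["ndre_std"],
            "ndvi": truth["ndvi_std"], "biomass": truth["biomass_std"],
        })
    elif scale == "natural":
        vals = pd.DataFrame({
            "area": truth["area_px"].astype(float), "height": truth["height_cm"],
            "volume": truth["area_px"] * truth["height_cm"],
            "ngrdi": truth["ngrdi"], "ndre": truth["ndre"], "ndvi": truth["ndvi"],
            "biomass": truth["biomass_kg"],
        })
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return pd.concat([keys, vals], axis=1)


def make_plot_map(layout: FieldLayout) -> PlotMap:
    """Plot map matching the layout, with sequential synthetic accession labels."""
    rows = []
    acc = 0
    for rep, i, j, blank in layout.positions():
        label = "" if blank else f"acc{acc % 212:03d}"
        if not blank:
            acc += 1
        rows.append((rep, i, j, label, blank))
    entries = pd.DataFrame(rows, columns=["replicate", "row", "col", "accession", "blank"])
    return PlotMap(entries=entries, replicates=layout.replicates,
                   rows=layout.rows, cols=layout.cols)


def _superellipse_order(h: int, w: int) -> np.ndarray:
    """Flat pixel indices of an (h, w) window ordered centre-out along a
    superellipse — growing n pixels yields a rectangle with eroded corners."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy = np.abs(yy - (h - 1) / 2.0) / (h / 2.0)
    dx = np.abs(xx - (w - 1) / 2.0) / (w / 2.0)
    score = dy**4 + dx**4
    return np.argsort(score.ravel(), kind="stable")


def plot_canopy_mask(layout: FieldLayout, area_px: int) -> np.ndarray:
    """Boolean canopy footprint of one plot rectangle with the given pixel
    count — the exact shape :func:`render_field_raster` paints."""
    ph, pw = layout.plot_shape_px
    if area_px > ph * pw:
        raise ValueError("area exceeds plot-rectangle capacity")
    sel = np.zeros(ph * pw, dtype=bool)
    sel[_superellipse_order(ph, pw)[:area_px]] = True
    return sel.reshape(ph, pw)


def _canopy_bands(ndvi, ndre, ngrdi, nir: float, blue: float) -> dict[str, float]:
    """Solve per-band canopy reflectances from target VI values at fixed NIR."""
    red = nir * (1.0 - ndvi) / (1.0 + ndvi)
    red_edge = nir * (1.0 - ndre) / (1.0 + ndre)
    green = red * (1.0 + ngrdi) / (1.0 - ngrdi)
    return {"blue": blue, "green": green, "red": red, "red_edge": red_edge, "nir": nir}


def render_field_raster(
    truth: pd.DataFrame,
    layout: FieldLayout,
    soil_reflectance: dict[str, float] | None = None,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
    canopy_nir: float = 0.35,
    canopy_blue: float = 0.05,
) -> tuple[MultibandFieldRaster, PlotMap]:
    """Render one month's truth table as a six-layer field raster.

    Each sown plot becomes a centred superellipse blob of exactly
    ``area_px`` canopy pixels inside its plot rectangle, with uniform canopy
    reflectance solved from the plot's true NDVI/NDRE/NGRDI; soil pixels get
    ``soil_reflectance``. The height layer is the true height on canopy
    pixels and 0 elsewhere. Additive Gaussian pixel noise (reflectance
    units) is applied to the spectral layers only.
    """
    soil = soil_reflectance or SOIL_REFLECTANCE
    if truth["month"].nunique() != 1:
        raise ValueError("render one month at a time")
    H, W = layout.raster_shape
    layers = {b: np.full((H, W), soil[b], dtype=np.float32)
              for b in ("blue", "green", "red", "red_edge", "nir")}
    layers["height"] = np.zeros((H, W), dtype=np.float32)

    ph, pw = layout.plot_shape_px
    order = _superellipse_order(ph, pw)
    for rec in truth.itertuples():
        r0, r1, c0, c1 = layout.plot_box(int(rec.replicate), int(rec.row), int(rec.col))
        n = int(rec.area_px)
        if n > ph * pw:
            raise ValueError(
                f"plot {(rec.replicate, rec.row, rec.col)} demands {n} canopy "
                f"pixels but its cell holds {ph * pw}"
            )
        sel = np.zeros(ph * pw, dtype=bool)
        sel[order[:n]] = True
        sel = sel.reshape(ph, pw)
        bands = _canopy_bands(rec.ndvi, rec.ndre, rec.ngrdi, canopy_nir, canopy_blue)
        for b, val in bands.items():
            layers[b][r0:r1, c0:c1][sel] = val
        layers["height"][r0:r1, c0:c1][sel] = rec.height_cm

    if pixel_noise_sd > 0:
        rng = np.random.default_rng(seed)
        for b in ("blue", "green", "red", "red_edge", "nir"):
            noise = rng.normal(0.0, pixel_noise_sd, (H, W)).astype(np.float32)
            layers[b] = np.clip(layers[b] + noise, 0.0, None)

    raster = MultibandFieldRaster(layers=layers, pixel_size=layout.gsd_cm)
    return raster, make_plot_map(layout)


def single_replicate(layout: FieldLayout, rep: int = 0) -> FieldLayout:
    """Restrict a layout to one replicate (used to render fields piecewise)."""
    blanks = tuple((0, r, c) for rp, r, c in layout.blanks if rp == rep)
    return replace(layout, replicates=1, blanks=blanks)
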