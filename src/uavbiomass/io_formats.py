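"""Raster and table I/O for the plot-phenotyping pipeline.

The pipeline's raster currency is a six-layer field image: five co-registered
reflectance bands (blue, green, red, red edge, NIR) plus a canopy-height
layer in centimetres, all on one pixel grid. Rasters are stored as
multi-layer TIFF (GeoTIFF tags, when present, are carried by tifffile but
never required). Plot maps, biomass records and feature tables are plain
CSV.

Conventions: pixel coordinates are 0-based (row, col) with row 0 at the top
of the raster (north-up); all boxes and masks are half-open [start, end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

#: canonical layer order in which rasters are written to disk
BAND_ORDER = ("blue", "green", "red", "red_edge", "nir", "height")

#: the five spectral layers (height is a geometric layer, never rescaled)
REFLECTANCE_BANDS = ("blue", "green", "red", "red_edge", "nir")

#: ordered harvest-month labels used throughout the package
MONTH_ORDER = ("May", "July", "September")


class RasterFormatError(ValueError):
    """A raster file does not satisfy the six-layer field-image contract."""


@dataclass
class MultibandFieldRaster:
    """Co-registered reflectance layers plus a canopy-height layer.

    Parameters
    ----------
    layers
        Mapping of layer name to 2-D float array. Must contain every name in
        :data:`BAND_ORDER`; all layers must share one shape. Reflectance
        layers are fractions (>= 0), ``height`` is in cm.
    pixel_size
        Ground sampling distance in cm/pixel.
    origin
        Coordinate convention tag; only ``"north-up"`` is produced here.
    """

    layers: dict[str, np.ndarray]
    pixel_size: float
    origin: str = "north-up"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [b for b in BAND_ORDER if b not in self.layers]
        if missing:
            raise RasterFormatError(f"{missing[0]} layer absent")
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        if len(set(shapes.values())) != 1:
            raise RasterFormatError(f"layer dimension mismatch: {shapes}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        self.layers = {
            name: np.asarray(arr, dtype=np.float32) for name, arr in self.layers.items()
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers["nir"].shape

    def band_stack(self, names: tuple[str, ...]) -> np.ndarray:
        """Stack the named layers along the last axis, shape (H, W, len(names))."""
        return np.stack([self.layers[n] for n in names], axis=-1)


def write_field_raster(raster: MultibandFieldRaster, path) -> None:
    """Write a six-layer raster as a multi-layer TIFF with a JSON sidecar tag."""
    stack = np.stack([raster.layers[b] for b in BAND_ORDER], axis=0)
    desc = json.dumps(
        {
            "layers": list(BAND_ORDER),
            "pixel_size_cm": raster.pixel_size,
            "origin": raster.origin,
        }
    )
    tifffile.imwrite(path, stack, description=desc, photometric="minisblack")


def read_field_raster(
    path,
    band_names: tuple[str, ...] | None = None,
    pixel_size: float | None = None,
) -> MultibandFieldRaster:
    """Read a multi-layer TIFF into a :class:`MultibandFieldRaster`.

    Layer names and pixel size are taken from the embedded JSON description
    written by :func:`write_field_raster`; for third-party files they may be
    supplied explicitly via ``band_names``/``pixel_size``.
    """
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if band_names is None or pixel_size is None:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    names = tuple(band_names or meta.get("layers", ()))
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_cm")
    if stack.ndim == 2:
        stack = stack[None]
    if not names:
        raise RasterFormatError("no layer names in file metadata or arguments")
    if stack.shape[0] < len(names):
        raise RasterFormatError(
            f"file has {stack.shape[0]} layers, {len(names)} names given"
        )
    layers = {name: stack[i] for i, name in enumerate(names)}
    if "height" not in layers:
        raise RasterFormatError("height layer absent")
    if px is None:
        raise RasterFormatError("pixel size missing from metadata and arguments")
    return MultibandFieldRaster(
        layers=layers, pixel_size=float(px), origin=meta.get("origin", "north-up")
    )


def compute_canopy_height(dsm: np.ndarray, dtm: np.ndarray) -> np.ndarray:
    """Canopy height in cm from surface and terrain elevation models (m).

    height = (DSM - DTM) * 100, clipped below at 0: negative differences are
    reconstruction noise over bare ground, not physical canopy depth.
    """
    dsm = np.asarray(dsm, dtype=float)
    dtm = np.asarray(dtm, dtype=float)
    if dsm.shape != dtm.shape:
        raise ValueError(f"DSM shape {dsm.shape} != DTM shape {dtm.shape}")
    return np.clip((dsm - dtm) * 100.0, 0.0, None)


def radiometric_scale(
    raster: MultibandFieldRaster,
    panel_mask: np.ndarray,
    nominal_reflectance: float = 0.60,
) -> MultibandFieldRaster:
    """Scale spectral layers so the reference panel reads its nominal reflectance.

    One multiplicative gain per band: gain_b = nominal / mean_b(panel pixels).
    The height layer is untouched.
    """
    panel_mask = np.asarray(panel_mask, dtype=bool)
    if panel_mask.shape != raster.shape:
        raise ValueError("panel mask shape does not match raster")
    if not panel_mask.any():
        raise ValueError("reference panel mask is empty")
    layers = dict(raster.layers)
    for band in REFLECTANCE_BANDS:
        panel_mean = float(raster.layers[band][panel_mask].mean())
        if panel_mean <= 0:
            raise ValueError(f"non-positive panel mean in band {band!r}")
        layers[band] = raster.layers[band] * (nominal_reflectance / panel_mean)
    return MultibandFieldRaster(
        layers=layers, pixel_size=raster.pixel_size, origin=raster.origin
    )


@dataclass
class PlotMap:
    """The designed plot grid of a field.

    ``entries`` has one row per designed position with columns
    ``replicate, row, col, accession, blank``; (replicate, row, col) is
    unique. Blank positions were never sown and carry no biomass record.
    """

    entries: pd.DataFrame
    replicates: int
    rows: int
    cols: int

    def __post_init__(self) -> None:
        keys = self.entries[["replicate", "row", "col"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate plot key {tuple(dup)}")

    @property
    def n_nonblank(self) -> int:
        return int((~self.entries["blank"]).sum())


def read_plot_map(path) -> PlotMap:
    df = pd.read_csv(path)
    required = {"replicate", "row", "col", "accession", "blank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plot map missing columns {sorted(missing)}")
    df["blank"] = df["blank"].astype(bool)
    return PlotMap(
        entries=df,
        replicates=int(df["replicate"].nunique()),
        rows=int(df["row"].max()) + 1,
        cols=int(df["col"].max()) + 1,
    )


def write_plot_map(plot_map: PlotMap, path) -> None:
    out = plot_map.entries.copy()
    out["blank"] = out["blank"].astype(int)
    out.to_csv(path, index=False)


def read_biomass(path, months: tuple[str, ...] = MONTH_ORDER) -> pd.DataFrame:
    """Read per-plot observed fresh biomass (kg), labeled by month and replicate."""
    df = pd.read_csv(path)
    required = {"replicate", "month", "row", "col", "biomass_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biomass table missing columns {sorted(missing)}")
    if (df["biomass_kg"] < 0).any():
        bad = df.loc[df["biomass_kg"] < 0].iloc[0]
        raise ValueError(f"negative biomass for plot {tuple(bad[['replicate','month','row','col']])}")
    unknown = set(df["month"]) - set(months)
    if unknown:
        raise ValueError(f"month labels {sorted(unknown)} outside declared set {months}")
    keys = df[["replicate", "month", "row", "col"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate biomass key {tuple(dup)}")
    return df


def write_biomass(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """One row per plot-month: replicate,row,col,month,area,height,volume,<VIs>."""
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
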