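"""Per-plot image features: vegetative area, canopy height, volume, and a
19-entry vegetation-index registry.

VIs are computed from plot-mean band reflectances (VI of means), matching a
workflow in which the segmentation tool reports the average of each spectral
band per plot. Pixel-wise VI averaging is available as an option.

The registry fixes the eleven indices the modeling narrative relies on
(NDVI, NDRE, NGRDI, SR, CI_RedEdge, CI_Green, GRVI, EVI, RVI, MCARI, EXG)
plus eight conventional fill-ins (GNDVI, SAVI, OSAVI, MSAVI, EVI2, EXR,
EXGR, TVI). It is user-extensible via :func:`register_vi`; the
feature-selection procedure does not depend on the fill-ins.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import REFLECTANCE_BANDS, MultibandFieldRaster
from .segmentation import PlotSegment

Bands = Mapping[str, float]


def _safe_div(num, den):
    if np.ndim(den) == 0:
        return num / den if den != 0 else math.nan
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _ndvi(b: Bands):
    return _safe_div(b["nir"] - b["red"], b["nir"] + b["red"])


def _ndre(b: Bands):
    return _safe_div(b["nir"] - b["red_edge"], b["nir"] + b["red_edge"])


def _ngrdi(b: Bands):
    return _safe_div(b["green"] - b["red"], b["green"] + b["red"])


def _sr(b: Bands):
    return _safe_div(b["nir"], b["red_edge"])


def _ci_rededge(b: Bands):
    return _safe_div(b["nir"], b["red_edge"]) - 1.0


def _ci_green(b: Bands):
    return _safe_div(b["nir"], b["green"]) - 1.0


def _grvi(b: Bands):
    return _safe_div(b["nir"], b["green"])


def _evi(b: Bands):
    return 2.5 * _safe_div(
        b["nir"] - b["red"], b["nir"] + 6.0 * b["red"] - 7.5 * b["blue"] + 1.0
    )


def _rvi(b: Bands):
    return _safe_div(b["nir"], b["red"])


def _mcari(b: Bands):
    return ((b["red_edge"] - b["red"]) - 0.2 * (b["red_edge"] - b["green"])) * _safe_div(
        b["red_edge"], b["red"]
    )


def _exg(b: Bands):
    return 2.0 * b["green"] - b["red"] - b["blue"]


def _gndvi(b: Bands):
    return _safe_div(b["nir"] - b["green"], b["nir"] + b["green"])


def _savi(b: Bands):
    return 1.5 * _safe_div(b["nir"] - b["red"], b["nir"] + b["red"] + 0.5)


def _osavi(b: Bands):
    return _safe_div(b["nir"] - b["red"], b["nir"] + b["red"] + 0.16)


def _msavi(b: Bands):
    nir, red = b["nir"], b["red"]
    disc = (2.0 * nir + 1.0) ** 2 - 8.0 * (nir - red)
    return (2.0 * nir + 1.0 - np.sqrt(np.maximum(disc, 0.0))) / 2.0


def _evi2(b: Bands):
    return 2.5 * _safe_div(b["nir"] - b["red"], b["nir"] + 2.4 * b["red"] + 1.0)


def _exr(b: Bands):
    return 1.4 * b["red"] - b["green"]


def _exgr(b: Bands):
    return _exg(b) - _exr(b)


def _tvi(b: Bands):
    return 0.5 * (120.0 * (b["nir"] - b["green"]) - 200.0 * (b["red"] - b["green"]))


#: ordered registry of the 19 vegetation indices
VI_REGISTRY: dict[str, Callable[[Bands], float]] = {
    "ndvi": _ndvi,
    "ndre": _ndre,
    "ngrdi": _ngrdi,
    "sr": _sr,
    "ci_rededge": _ci_rededge,
    "ci_green": _ci_green,
    "grvi": _grvi,
    "evi": _evi,
    "rvi": _rvi,
    "mcari": _mcari,
    "exg": _exg,
    "gndvi": _gndvi,
    "savi": _savi,
    "osavi": _osavi,
    "msavi": _msavi,
    "evi2": _evi2,
    "exr": _exr,
    "exgr": _exgr,
    "tvi": _tvi,
}

#: feature count contract: area + height + volume + the 19 VIs
N_FEATURES = 3 + len(VI_REGISTRY)


def register_vi(name: str, func: Callable[[Bands], float]) -> None:
    """Add a custom index to the registry (callable over band means)."""
    VI_REGISTRY[name] = func


def compute_vi(name: str, band_means: Bands) -> float:
    """Evaluate one registered index on plot-mean reflectances.

    A zero denominator yields NaN (undefined-value marker), not an exception.
    """
    if name not in VI_REGISTRY:
        raise KeyError(f"unknown vegetation index {name!r}")
    val = VI_REGISTRY[name](band_means)
    return float(val) if np.ndim(val) == 0 else val


def extract_plot_features(
    raster: MultibandFieldRaster,
    segments: Sequence[PlotSegment],
    month: str | None = None,
    pixelwise_vi: bool = False,
) -> pd.DataFrame:
    """Aggregate each plot segment into its 22-feature record.

    Per segment: ``area`` = vegetation pixel count; band means over
    vegetation pixels only; ``height`` = mean canopy-height layer over
    vegetation pixels (cm); ``volume`` = area * height (pixel*cm); the 19
    registry VIs from the band means. Empty-mask plots yield area 0, height
    and volume 0, and NaN VI markers.
    """
    records = []
    H, W = raster.shape
    for seg in segments:
        r0, r1, c0, c1 = seg.box
        if not (0 <= r0 <= r1 <= H and 0 <= c0 <= c1 <= W):
            raise ValueError(f"segment {seg.key} outside raster bounds")
        rec: dict = {"replicate": seg.replicate, "row": seg.row, "col": seg.col}
        if month is not None:
            rec["month"] = month
        mask = seg.mask
        area = int(mask.sum())
        rec["area"] = area
        if area == 0:
            rec["height"] = 0.0
            rec["volume"] = 0.0
            for name in VI_REGISTRY:
                rec[name] = math.nan
            records.append(rec)
            continue
        window = {
            band: raster.layers[band][r0:r1, c0:c1][mask]
            for band in REFLECTANCE_BANDS
        }
        height = float(raster.layers["height"][r0:r1, c0:c1][mask].mean())
        rec["height"] = height
        rec["volume"] = area * height
        if pixelwise_vi:
            for name in VI_REGISTRY:
                vals = VI_REGISTRY[name]({b: window[b].astype(float) for b in window})
                rec[name] = float(np.nanmean(vals))
        else:
            means = {band: float(px.mean()) for band, px in window.items()}
            for name in VI_REGISTRY:
                rec[name] = compute_vi(name, means)
        records.append(rec)
    cols = ["replicate", "row", "col"]
    if month is not None:
        cols.append("month")
    cols += ["area", "height", "volume", *VI_REGISTRY]
    return pd.DataFrame.from_records(records, columns=cols)
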