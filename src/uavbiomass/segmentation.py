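"""Fully automatic plot segmentation.

Pipeline: (1) k-means clustering of pixels in a chosen channel space
(default red + NIR), (2) vegetation-class selection by mean NDVI,
(3) automatic grid detection from projection profiles of the vegetation
mask, (4) per-cell boundary refinement to the connected canopy component
nearest each cell centre, capped at the midlines to neighbouring cells.

Grid detection uses projection profiles: vegetation counts are projected
onto rows and columns, smoothed with a moving average, and cut at the local
minima between consecutive peaks. Cluster labels from k-means are arbitrary,
so the vegetation class is identified by its mean NDVI — the same criterion
the pipeline uses to define vegetative area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.cluster import KMeans

from .io_formats import MultibandFieldRaster, PlotMap

Interval = tuple[int, int]


@dataclass
class PixelClassMap:
    """Per-pixel integer class labels with the fitted class centroids."""

    labels: np.ndarray  # 2-D int array, values in {0..k-1}
    k: int
    centroids: np.ndarray  # (k, n_channels) in clustering channel space
    channels: tuple[str, ...]


@dataclass
class PlotSegment:
    """A detected plot: grid identity, bounding box, vegetation mask.

    ``box`` is (row_start, row_stop, col_start, col_stop), half-open, in
    raster pixel coordinates; ``mask`` is boolean with box shape.
    """

    replicate: int
    row: int
    col: int
    box: tuple[int, int, int, int]
    mask: np.ndarray
    blank: bool = False

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.replicate, self.row, self.col)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def cluster_pixels(
    raster: MultibandFieldRaster,
    channels: tuple[str, ...] = ("red", "nir"),
    k: int = 3,
    seed: int = 0,
) -> PixelClassMap:
    """k-means classification of all pixels in the named channel space.

    k-means++ initialisation with a fixed seed, tolerance 1e-4, at most 300
    iterations; a single seeded initialisation keeps labels deterministic.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = raster.band_stack(channels).reshape(-1, len(channels)).astype(np.float64)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"fewer distinct values than k ({n_distinct} < {k})")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, tol=1e-4, max_iter=300,
        random_state=seed,
    ).fit(X)
    labels = km.labels_.reshape(raster.shape)
    return PixelClassMap(labels=labels, k=k, centroids=km.cluster_centers_, channels=tuple(channels))


def select_vegetation_class(
    classes: PixelClassMap, raster: MultibandFieldRaster
) -> np.ndarray:
    """Boolean mask of the class with the highest mean NDVI.

    Warns if even the selected class has mean NDVI below 0 (no vegetation
    detected); raises if the top two classes tie in mean NDVI beyond 1e-9
    (ambiguous clustering).
    """
    nir = raster.layers["nir"].astype(np.float64)
    red = raster.layers["red"].astype(np.float64)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / denom, np.nan)
    means = np.array(
        [np.nanmean(ndvi[classes.labels == c]) for c in range(classes.k)]
    )
    order = np.argsort(means)[::-1]
    if classes.k > 1 and abs(means[order[0]] - means[order[1]]) <= 1e-9:
        raise ValueError("ambiguous clustering: top classes tie in mean NDVI")
    best = int(order[0])
    if means[best] < 0:
        warnings.warn("no vegetation detected: best class mean NDVI < 0")
    return classes.labels == best


def _dominant_period(profile: np.ndarray) -> float:
    """Dominant spatial period of a 1-D profile via the FFT magnitude peak."""
    p = profile - profile.mean()
    spec = np.abs(np.fft.rfft(p))
    if len(spec) < 2:
        return float(len(profile))
    kk = int(np.argmax(spec[1:])) + 1
    return len(profile) / kk


def _profile_intervals(
    profile: np.ndarray, expected: int | None
) -> list[Interval]:
    """Cut a projection profile into per-plot intervals at inter-peak minima."""
    nz = np.flatnonzero(profile)
    if nz.size == 0:
        raise ValueError("empty vegetation mask")
    lo, hi = int(nz[0]), int(nz[-1]) + 1
    p = profile[lo:hi].astype(float)
    if expected is not None and expected > 0:
        pitch = len(p) / expected
    else:
        pitch = _dominant_period(p)
    window = max(1, int(round(0.25 * pitch)))
    kernel = np.ones(window) / window
    sm = np.convolve(p, kernel, mode="same")
    # zero-pad so peaks at the support edges are found
    padded = np.concatenate([[0.0], sm, [0.0]])
    peaks, _ = signal.find_peaks(padded, distance=max(1, int(round(0.5 * pitch))))
    peaks = peaks - 1
    if peaks.size == 0:  # single plateau blob
        peaks = np.array([int(np.argmax(sm))])
    cuts = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        cuts.append(int(np.argmin(sm[a : b + 1])) + int(a))
    starts = [lo] + [lo + c for c in cuts]
    stops = [lo + c for c in cuts] + [hi]
    return list(zip(starts, stops))


def detect_plot_grid(
    mask: np.ndarray, expected: tuple[int, int] | None = None
) -> tuple[list[Interval], list[Interval]]:
    """Detect row and column plot boundaries from a vegetation mask.

    Returns sorted, non-overlapping half-open intervals along each axis. The
    smoothing window is 0.25x the expected plot pitch when ``expected``
    (rows, cols) is given, else 0.25x the dominant FFT period of the
    profile. Raises if the detected counts differ from ``expected``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty vegetation mask")
    row_profile = mask.sum(axis=1)
    col_profile = mask.sum(axis=0)
    exp_rows, exp_cols = expected if expected is not None else (None, None)
    rows = _profile_intervals(row_profile, exp_rows)
    cols = _profile_intervals(col_profile, exp_cols)
    if expected is not None and (len(rows), len(cols)) != tuple(expected):
        raise ValueError(
            f"detected grid {len(rows)}x{len(cols)} != expected "
            f"{expected[0]}x{expected[1]}"
        )
    return rows, cols


def _midline_windows(intervals: list[Interval], limit: int) -> list[Interval]:
    """Expand each grid interval to the midlines toward its neighbours."""
    windows = []
    for i, (a, b) in enumerate(intervals):
        lo = 0 if i == 0 else (intervals[i - 1][1] + a) // 2
        hi = limit if i == len(intervals) - 1 else (b + intervals[i + 1][0]) // 2
        windows.append((lo, hi))
    return windows


def refine_plot_boundaries(
    mask: np.ndarray,
    grid: tuple[list[Interval], list[Interval]],
    plot_map: PlotMap,
) -> list[PlotSegment]:
    """Snap each grid cell to its canopy blob; label segments by plot key.

    For every cell, the search window extends to the midlines toward
    neighbouring cells (raster edge for border cells), the vegetation pixels
    inside the window are split into connected components, and the component
    whose centroid is nearest the cell centre becomes the plot's mask.
    Windows partition the raster, so no vegetation pixel is assigned twice.
    Blank plots always yield empty masks.

    Replicates are assumed stacked along the row axis: detected row count
    must equal replicates x rows of the plot map.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = grid
    n_rep, n_row, n_col = plot_map.replicates, plot_map.rows, plot_map.cols
    if len(rows) != n_rep * n_row or len(cols) != n_col:
        raise ValueError(
            f"grid {len(rows)}x{len(cols)} does not match plot map "
            f"{n_rep}x{n_row}x{n_col}"
        )
    row_windows = _midline_windows(rows, mask.shape[0])
    col_windows = _midline_windows(cols, mask.shape[1])
    blank_lookup = {
        (int(r.replicate), int(r.row), int(r.col)): bool(r.blank)
        for r in plot_map.entries.itertuples()
    }
    reps = sorted(plot_map.entries["replicate"].unique())
    segments: list[PlotSegment] = []
    for gi, (ra, rb) in enumerate(rows):
        rep = reps[gi // n_row]
        row_idx = gi % n_row
        wr0, wr1 = row_windows[gi]
        for gj, (ca, cb) in enumerate(cols):
            key = (int(rep), row_idx, gj)
            if key not in blank_lookup:
                continue
            wc0, wc1 = col_windows[gj]
            cell_box = (ra, rb, ca, cb)
            if blank_lookup[key]:
                segments.append(
                    PlotSegment(*key, box=cell_box,
                                mask=np.zeros((rb - ra, cb - ca), dtype=bool),
                                blank=True)
                )
                continue
            window = mask[wr0:wr1, wc0:wc1]
            labeled, n_comp = ndimage.label(window)
            if n_comp == 0:
                segments.append(
                    PlotSegment(*key, box=cell_box,
                                mask=np.zeros((rb - ra, cb - ca), dtype=bool))
                )
                continue
            center = ((ra + rb) / 2 - wr0, (ca + cb) / 2 - wc0)
            centroids = ndimage.center_of_mass(window, labeled, range(1, n_comp + 1))
            d2 = [
                (cy - center[0]) ** 2 + (cx - center[1]) ** 2 for cy, cx in centroids
            ]
            chosen = int(np.argmin(d2)) + 1
            comp = labeled == chosen
            sl = ndimage.find_objects(comp.astype(np.int8))[0]
            box = (
                wr0 + sl[0].start, wr0 + sl[0].stop,
                wc0 + sl[1].start, wc0 + sl[1].stop,
            )
            segments.append(PlotSegment(*key, box=box, mask=comp[sl]))
    return segments
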