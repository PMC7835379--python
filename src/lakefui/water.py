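"""Adaptive lake extraction from the 1640 nm band.

Each connected water body gets its own threshold, found as the histogram
valley of the SWIR reflectance over the body plus a 1.5x buffer zone — the
modified histogram-bimodal approach.  QA-flagged pixels are removed, the
shoreline is eroded by one pixel against land-adjacency contamination, and
optically shallow rim pixels are excluded by a blue-band threshold.  Masks
accumulated over the record yield the >30%-occurrence normal water mask
with centroid and area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .sceneio import QA, Affine, SceneStack

__all__ = [
    "LakeRegion",
    "NormalWaterMask",
    "initial_water_mask",
    "connected_components",
    "build_buffer",
    "find_threshold",
    "refine_lake",
    "normal_water_mask",
]

T0_DEFAULT = 0.04
T1_DEFAULT = 0.12
BIN_WIDTH_DEFAULT = 0.002
SHALLOW_BLUE_DEFAULT = 0.06
OCCURRENCE_DEFAULT = 0.30

_SQUARE = np.ones((3, 3), dtype=bool)


@dataclass
class LakeRegion:
    lake_id: str
    component_mask: np.ndarray
    buffer_mask: np.ndarray | None = None
    threshold: float | None = None
    threshold_fallback: bool = False
    refined_mask: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def area_pixels(self) -> int:
        return int(self.component_mask.sum())


@dataclass
class NormalWaterMask:
    lake_id: str
    mask: np.ndarray
    area_km2: float
    centroid_lon: float
    centroid_lat: float
    freezing: bool = False


def initial_water_mask(scene: SceneStack) -> np.ndarray:
    """Rough water area from QA: inland-water bit set, no obscuring bit."""
    qa = scene.qa
    return ((qa & QA.INLAND_WATER) != 0) & ((qa & QA.OBSCURED) == 0)


def connected_components(
    mask: np.ndarray,
    min_area_km2: float = 25.0,
    pixel_size_m: float = 500.0,
    scene_id: str = "scene",
) -> list[LakeRegion]:
    """8-connected components above the area floor, in row-major order."""
    labels, n = ndimage.label(np.asarray(mask, bool), structure=_SQUARE)
    pixel_km2 = (pixel_size_m / 1000.0) ** 2
    regions = []
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() * pixel_km2 < min_area_km2:
            continue
        regions.append(LakeRegion(lake_id="", component_mask=comp))
    # deterministic ordering by first (row-major) pixel of each component
    regions.sort(key=lambda r: int(np.flatnonzero(r.component_mask.ravel())[0]))
    for i, region in enumerate(regions):
        region.lake_id = f"{scene_id}_{i + 1}"
    return regions


def build_buffer(region: LakeRegion, factor: float = 1.5) -> LakeRegion:
    """Dilate the component until the expanded area reaches ``factor`` x.

    The first dilation ring that crosses the target is included, so the
    expanded area lands in [target, target + one ring].  If the grid edge
    truncates growth before the target is reached, a warning is recorded.
    """
    comp = region.component_mask
    if not comp.any():
        raise ValueError("empty component")
    target = factor * comp.sum()
    expanded = comp.copy()
    while expanded.sum() < target:
        grown = ndimage.binary_dilation(expanded, structure=_SQUARE)
        if grown.sum() == expanded.sum():  # saturated the grid
            region.warnings.append(
                f"{region.lake_id}: buffer truncated by grid edge "
                f"({expanded.sum()} px < target {target:.0f})"
            )
            break
        expanded = grown
    region.buffer_mask = expanded
    return region


def find_threshold(
    swir_values: np.ndarray,
    t0: float = T0_DEFAULT,
    t1: float = T1_DEFAULT,
    bin_width: float = BIN_WIDTH_DEFAULT,
    valley_ratio: float = 0.5,
) -> tuple[float, bool]:
    """Histogram-valley threshold within [t0, t1].

    Returns ``(threshold, fallback)``.  The threshold is the centre of the
    minimum-count bin inside the window, ties broken toward lower
    reflectance.  If no bin lies in the window, or the window minimum is not
    a genuine valley (its count is not below ``valley_ratio`` times the
    smaller of the two flanking peaks — e.g. a unimodal or flat histogram),
    the midpoint (t0+t1)/2 is returned with the fallback flag set.
    """
    values = np.asarray(swir_values, dtype=float)
    values = values[np.isfinite(values)]
    fallback = (t0 + t1) / 2.0
    if values.size == 0:
        return fallback, True
    edges = np.arange(0.0, max(values.max(), t1) + 2 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    in_window = (centers >= t0) & (centers <= t1)
    if not in_window.any():
        return fallback, True
    window_counts = counts[in_window]
    window_centers = centers[in_window]
    i_min = int(np.argmin(window_counts))  # argmin takes the first = lower bin
    valley_count = window_counts[i_min]
    below = counts[centers < t0]
    above = counts[centers > t1]
    if below.size == 0 or above.size == 0:
        return fallback, True
    peak = min(below.max(), above.max())
    if peak <= 0 or valley_count >= valley_ratio * peak:
        return fallback, True
    return float(window_centers[i_min]), False


def refine_lake(
    scene: SceneStack,
    region: LakeRegion,
    *,
    swir_band: str = "swir1640",
    blue_band: str = "blue",
    blue: np.ndarray | None = None,
    shallow_blue_threshold: float = SHALLOW_BLUE_DEFAULT,
    t0: float = T0_DEFAULT,
    t1: float = T1_DEFAULT,
    bin_width: float = BIN_WIDTH_DEFAULT,
) -> LakeRegion:
    """Threshold, de-flag, erode and de-shallow one lake for one scene.

    Sets ``region.threshold`` (found over QA-clean pixels of the expanded
    area) and ``region.refined_mask``; an all-removed lake gets an empty
    refined mask, meaning unobserved on this date.

    ``scene`` must carry the *uncorrected* SWIR band: the water-leaving
    correction subtracts the NIR-SWIR minimum and flattens the water/land
    contrast the histogram threshold relies on.  The shallow-water test
    should instead see corrected reflectance; pass it via ``blue``.
    """
    if region.buffer_mask is None:
        build_buffer(region)
    swir = scene.band(swir_band)
    blue = scene.band(blue_band) if blue is None else blue
    bad = (scene.qa & QA.BAD) != 0
    sample = swir[region.buffer_mask & ~bad]
    threshold, fb = find_threshold(sample, t0=t0, t1=t1, bin_width=bin_width)
    region.threshold = threshold
    region.threshold_fallback = fb
    water = region.buffer_mask & (swir < threshold) & ~bad
    water = ndimage.binary_erosion(water, structure=_SQUARE)
    water &= blue <= shallow_blue_threshold
    region.refined_mask = water
    return region


def normal_water_mask(
    refined_masks: list[np.ndarray],
    observable_masks: list[np.ndarray],
    *,
    lake_id: str = "lake",
    occurrence_min: float = OCCURRENCE_DEFAULT,
    transform: Affine | None = None,
    pixel_size_m: float = 500.0,
    freezing: bool = False,
) -> NormalWaterMask:
    """Occurrence-frequency mask over the record.

    A pixel is kept iff (#dates water) / (#dates observable) exceeds
    ``occurrence_min``; the denominator counts only dates where the pixel is
    QA-observable.  The centroid is the mean of member pixel centres mapped
    through the affine transform.
    """
    if not refined_masks:
        raise ValueError("need at least one date")
    if len(refined_masks) != len(observable_masks):
        raise ValueError("refined and observable mask lists differ in length")
    water_count = np.sum(np.asarray(refined_masks, dtype=bool), axis=0)
    obs_count = np.sum(np.asarray(observable_masks, dtype=bool), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(obs_count > 0, water_count / np.maximum(obs_count, 1), 0.0)
    mask = freq > occurrence_min
    area_km2 = float(mask.sum()) * (pixel_size_m / 1000.0) ** 2
    if mask.any():
        rows, cols = np.nonzero(mask)
        tr = transform or Affine(0.0, pixel_size_m / 111320.0 * 1.0, 0.0,
                                 -pixel_size_m / 111320.0)
        xs, ys = tr.pixel_center(rows.mean(), cols.mean())
        lon, lat = float(xs), float(ys)
    else:
        warnings.warn(f"{lake_id}: empty normal water mask")
        lon = lat = float("nan")
    return NormalWaterMask(
        lake_id=lake_id, mask=mask, area_km2=area_km2,
        centroid_lon=lon, centroid_lat=lat, freezing=freezing,
    )


def observable_mask(scene: SceneStack) -> np.ndarray:
    """Pixels where water vs land can be decided (no cloud/shadow/ice)."""
    return (scene.qa & QA.OBSCURED) == 0
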