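"""Synthetic multiband scenes with known ground truth.

Lakes are rendered as connected low-SWIR regions embedded in bright land.
Each lake carries a true colour class whose red/green/blue reflectances are
obtained by inverting the colorimetric pipeline, so the forward retrieval
has an exact oracle.  The observation model is::

    band = intrinsic water-leaving reflectance + residual_level + noise

i.e. an additive, spectrally flat sky/aerosol residual plus optional
Gaussian noise — exactly the structure the NIR-SWIR minimum correction is
designed to remove.  Clouds are random smooth blobs recorded only in the QA
bitmask; QA truth is authoritative.

Randomness: ``SceneSpec.seed`` feeds a ``numpy.random.SeedSequence``; child
streams are spawned in a fixed order (noise, clouds, outliers), and series
generation spawns one stream pair per date index, so masks are identical
across seeds while noise fields differ.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from skimage import draw as _draw

from . import colorimetry as cm
from .sceneio import DEFAULT_TRANSFORM, QA, SceneStack

__all__ = [
    "LakeSpec",
    "SceneSpec",
    "SceneTruth",
    "BandValues",
    "fui_to_reflectance",
    "generate_scene",
    "generate_series",
]

#: fixed tristimulus sum used by the colour inversion (arbitrary but stable)
BRIGHTNESS = 0.4

#: intrinsic (pre-residual) land spectrum
LAND_SPECTRUM = {"red": 0.10, "green": 0.09, "blue": 0.06, "nir": 0.25}

#: intrinsic shallow-water blue boost (pushes blue over the shallow threshold)
SHALLOW_BLUE_BOOST = 0.08


#: highest class whose corrected angle is reachable under the deviation
#: correction (alpha + delta(alpha) has a global minimum near 41.3 deg,
#: above the look-up-table angles of classes 17..21)
MAX_DELTA_CLASS = 16


class BandValues(NamedTuple):
    red: float
    green: float
    blue: float
    nir: float
    swir1640: float


@dataclass
class LakeSpec:
    """One lake: geometry in pixel coordinates plus its true colour history.

    ``shape`` is either ``("ellipse", (row_c, col_c, r_row, r_col))`` or
    ``("polygon", (rows, cols))`` with vertex arrays in pixel coordinates.
    """

    shape: tuple
    base_fui: int = 5
    true_fui_by_date: dict[_dt.date, int] = field(default_factory=dict)
    freezing: bool = False
    shallow_margin_pixels: int = 0

    def __post_init__(self) -> None:
        for k in [self.base_fui, *self.true_fui_by_date.values()]:
            if not 1 <= int(k) <= 21:
                raise ValueError(f"FUI class {k} outside 1..21")

    def fui_for(self, date: _dt.date | None) -> int:
        if date is not None and date in self.true_fui_by_date:
            return self.true_fui_by_date[date]
        return self.base_fui

    def rasterize(self, grid_shape: tuple[int, int]) -> np.ndarray:
        kind, params = self.shape
        mask = np.zeros(grid_shape, dtype=bool)
        if kind == "ellipse":
            rr, cc = _draw.ellipse(*params, shape=grid_shape)
        elif kind == "polygon":
            rr, cc = _draw.polygon(*params, shape=grid_shape)
        else:
            raise ValueError(f"unknown lake geometry kind {kind!r}")
        mask[rr, cc] = True
        return mask


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (or of every scene in a series)."""

    grid_shape: tuple[int, int]
    lakes: list[LakeSpec]
    pixel_size: float = 500.0
    land_swir_level: float = 0.2
    water_swir_level: float = 0.02
    residual_level: float = 0.0
    cloud_fraction: float = 0.0
    noise_sd: float = 0.0
    compensate_delta: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError("cloud_fraction must be in [0, 1]")
        if self.water_swir_level >= self.land_swir_level:
            raise ValueError("water SWIR level must be below land SWIR level")
        if self.residual_level < 0:
            raise ValueError("residual_level must be non-negative")


@dataclass
class SceneTruth:
    """Ground truth aligned with a generated scene."""

    water_mask: np.ndarray
    fui_raster: np.ndarray          # per-pixel true class, 0 on land
    lake_masks: list[np.ndarray]
    true_fui: list[int]             # per lake, at this scene's date
    qa_truth: np.ndarray
    outliers: list[tuple[int, _dt.date, int]] = field(default_factory=list)
    # (lake index, date, rendered outlier class)


_MINV = np.linalg.inv(cm.RGB_TO_XYZ)


def _alpha_for_class(fui_class: int, compensate_delta: bool) -> tuple[float, float]:
    """Target hue angle and locus radius for a class.

    With ``compensate_delta`` the returned angle alpha* solves
    ``alpha* + delta(alpha*) == alpha_k``, so that the satellite-convention
    retrieval (which adds the deviation term) lands exactly on the class
    angle.  Without it the look-up-table angle is used directly.
    """
    lut = cm.load_lut()
    alpha_k = float(lut.alpha[fui_class - 1])
    radius = float(np.hypot(lut.x[fui_class - 1] - 1 / 3, lut.y[fui_class - 1] - 1 / 3))
    if not compensate_delta:
        return alpha_k, radius

    def f(a: float) -> float:
        return a + cm.delta_correction(a)[0] - alpha_k

    # scan a bracket around the class angle for the root nearest to it
    grid = np.linspace(alpha_k - 80.0, alpha_k + 80.0, 161)
    vals = np.array([f(a) for a in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, grid[i], grid[i + 1]))
    if not roots:
        # alpha + delta(alpha) has a global minimum near 41.3 deg, so the
        # corrected angles of classes 17..21 cannot be produced by any hue;
        # those classes are not representable under the satellite convention.
        raise ValueError(
            f"class {fui_class} is not representable with delta compensation: "
            "alpha + delta(alpha) never reaches its look-up-table angle"
        )
    return min(roots, key=lambda a: abs(a - alpha_k)), radius


def _rgb_for_class(fui_class: int, compensate_delta: bool) -> tuple[float, float, float]:
    alpha, radius = _alpha_for_class(fui_class, compensate_delta)
    rad = np.radians(alpha)
    for _ in range(60):
        x = 1 / 3 + radius * np.cos(rad)
        y = 1 / 3 + radius * np.sin(rad)
        xyz = np.array([x, y, 1.0 - x - y]) * BRIGHTNESS
        rgb = _MINV @ xyz
        if np.all(rgb >= 0):
            return tuple(float(v) for v in rgb)
        radius *= 0.9  # pull toward the white point, hue unchanged
    raise RuntimeError(f"could not find non-negative RGB for class {fui_class}")


def fui_to_reflectance(
    fui_class: int,
    residual_level: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    compensate_delta: bool = False,
    water_swir_level: float = 0.02,
) -> BandValues:
    """Invert the colour retrieval: class -> five-band water spectrum.

    The intrinsic NIR reflectance is zero (clear-water assumption), so after
    subtracting the NIR-SWIR minimum the visible bands return exactly to
    their intrinsic values and the forward pipeline classifies back to
    ``fui_class``.  ``compensate_delta`` pre-shifts the hue so that the
    retrieval *with* the band-deviation correction recovers the class.
    """
    fui_class = int(fui_class)
    if not 1 <= fui_class <= 21:
        raise ValueError(f"fui_class must be in 1..21, got {fui_class}")
    r, g, b = _rgb_for_class(fui_class, compensate_delta)
    values = np.array([r, g, b, 0.0, water_swir_level]) + residual_level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=5)
    return BandValues(*values)


def _cloud_mask(shape: tuple[int, int], fraction: float,
                rng: np.random.Generator) -> np.ndarray:
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    fld = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    return fld >= np.quantile(fld, 1.0 - fraction)


def _validate_lakes(spec: SceneSpec) -> list[np.ndarray]:
    masks = [lake.rasterize(spec.grid_shape) for lake in spec.lakes]
    occupancy = np.zeros(spec.grid_shape, dtype=np.int16)
    for m in masks:
        occupancy += m
    if (occupancy > 1).any():
        raise ValueError("lakes overlap")
    # touching = adjacent under 8-connectivity counts as touching as well
    for i, m in enumerate(masks):
        grown = ndimage.binary_dilation(m, structure=np.ones((3, 3), bool))
        for j, other in enumerate(masks):
            if j != i and (grown & other).any():
                raise ValueError(f"lakes {i} and {j} touch")
    edge = np.zeros(spec.grid_shape, dtype=bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    for i, m in enumerate(masks):
        if (m & edge).any():
            raise ValueError(f"lake {i} touches the grid edge")
    return masks


def generate_scene(
    spec: SceneSpec,
    date: _dt.date = _dt.date(2000, 7, 4),
    *,
    rendered_fui: list[int] | None = None,
    ice_lakes: set[int] | None = None,
    rng_streams: tuple[np.random.Generator, np.random.Generator] | None = None,
) -> tuple[SceneStack, SceneTruth]:
    """Render one scene and its aligned truth.

    ``rendered_fui`` overrides the class drawn for each lake (used by
    :func:`generate_series` to plant outliers without touching the truth
    classes); ``ice_lakes`` marks lake indices whose pixels receive the
    snow/ice QA flag.
    """
    lake_masks = _validate_lakes(spec)
    if rng_streams is None:
        ss = np.random.SeedSequence(spec.seed)
        noise_rng, cloud_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    else:
        noise_rng, cloud_rng = rng_streams

    shape = spec.grid_shape
    bands = {
        "red": np.full(shape, LAND_SPECTRUM["red"]),
        "green": np.full(shape, LAND_SPECTRUM["green"]),
        "blue": np.full(shape, LAND_SPECTRUM["blue"]),
        "nir": np.full(shape, LAND_SPECTRUM["nir"]),
        "swir1640": np.full(shape, spec.land_swir_level),
    }
    water_mask = np.zeros(shape, dtype=bool)
    fui_raster = np.zeros(shape, dtype=np.int16)
    true_fui = []
    qa = np.zeros(shape, dtype=np.uint16)
    square = np.ones((3, 3), bool)

    for i, (lake, mask) in enumerate(zip(spec.lakes, lake_masks)):
        truth_class = lake.fui_for(date)
        shown_class = rendered_fui[i] if rendered_fui is not None else truth_class
        bv = fui_to_reflectance(
            shown_class,
            compensate_delta=spec.compensate_delta,
            water_swir_level=spec.water_swir_level,
        )
        for name, value in zip(BandValues._fields, bv):
            bands[name][mask] = value
        if lake.shallow_margin_pixels > 0:
            interior = ndimage.binary_erosion(
                mask, structure=square, iterations=lake.shallow_margin_pixels
            )
            rim = mask & ~interior
            bands["blue"][rim] += SHALLOW_BLUE_BOOST
        water_mask |= mask
        fui_raster[mask] = truth_class
        true_fui.append(truth_class)
        qa[mask] |= QA.INLAND_WATER
        if ice_lakes and i in ice_lakes:
            qa[mask] |= QA.SNOW_ICE

    # mixed pixels: land pixels touching water
    boundary = ndimage.binary_dilation(water_mask, structure=square) & ~water_mask
    qa[boundary] |= QA.MIXED

    clouds = _cloud_mask(shape, spec.cloud_fraction, cloud_rng)
    qa[clouds] |= QA.CLOUD

    for name in bands:
        bands[name] = bands[name] + spec.residual_level
        if spec.noise_sd > 0:
            bands[name] = bands[name] + noise_rng.normal(0.0, spec.noise_sd, shape)

    scene = SceneStack(
        date=date, bands=bands, qa=qa,
        transform=DEFAULT_TRANSFORM, pixel_size_m=spec.pixel_size,
    )
    truth = SceneTruth(
        water_mask=water_mask, fui_raster=fui_raster, lake_masks=lake_masks,
        true_fui=true_fui, qa_truth=qa.copy(),
    )
    return scene, truth


def _seasonal_class(base: int, amplitude: float, date: _dt.date) -> int:
    doy = date.timetuple().tm_yday
    value = base + amplitude * np.sin(2.0 * np.pi * (doy - 120) / 365.25)
    return int(np.clip(round(value), 1, 21))


def generate_series(
    spec: SceneSpec,
    dates: list[_dt.date],
    seasonal_amplitude: float = 0.0,
    outlier_rate: float = 0.0,
) -> list[tuple[SceneStack, SceneTruth]]:
    """Render a dated sequence of scenes with seasonal truth and outliers.

    Per-lake truth follows ``base_fui + amplitude*sin`` rounded to classes.
    With probability ``outlier_rate`` per lake and date, the *rendered*
    class jumps to the far end of the scale — the brightest class the
    convention can represent, or class 1 for already-bright lakes — the way
    undetected thin cloud or glint corrupts a whole composite; truth is
    unchanged and the event is recorded in the scene truth.  Freezing lakes
    carry snow/ice QA flags from November through April.
    """
    if not dates:
        raise ValueError("empty date list")
    if sorted(set(dates)) != list(dates):
        raise ValueError("dates must be sorted and unique")
    ss = np.random.SeedSequence(spec.seed)
    outlier_rng = np.random.default_rng(ss.spawn(1)[0])
    cap = MAX_DELTA_CLASS if spec.compensate_delta else 21
    out = []
    for di, date in enumerate(dates):
        # fixed per-date spawn order keeps scenes independent of list length
        date_ss = np.random.SeedSequence([spec.seed, 1000 + di])
        noise_rng, cloud_rng = (np.random.default_rng(c) for c in date_ss.spawn(2))
        rendered = []
        truth_classes = []
        outlier_events = []
        ice = set()
        for li, lake in enumerate(spec.lakes):
            k = lake.true_fui_by_date.get(
                date, _seasonal_class(lake.base_fui, seasonal_amplitude, date)
            )
            k = int(min(k, cap))
            lake.true_fui_by_date[date] = k
            truth_classes.append(k)
            shown = k
            if outlier_rate > 0 and outlier_rng.random() < outlier_rate:
                shown = cap if k <= (1 + cap) // 2 else 1
                outlier_events.append((li, date, shown))
            rendered.append(shown)
            if lake.freezing and (date.month >= 11 or date.month <= 4):
                ice.add(li)
        scene, truth = generate_scene(
            spec, date, rendered_fui=rendered, ice_lakes=ice,
            rng_streams=(noise_rng, cloud_rng),
        )
        truth.outliers = outlier_events
        out.append((scene, truth))
    return out
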