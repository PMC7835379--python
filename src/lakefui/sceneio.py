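"""Scene container and raster I/O.

A :class:`SceneStack` holds one dated multiband reflectance composite plus an
integer QA bitmask and a simple affine georeference.  Scenes are stored as
multiband TIFF files with band names, date, transform and CRS embedded as a
JSON document in the TIFF description tag (keeps the whole pipeline free of
GDAL bindings while remaining a plain georeferenced raster stack).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["QA", "Affine", "SceneStack", "read_scene", "write_scene",
           "read_mask", "write_mask"]


class QA:
    """Bit positions of the per-pixel quality mask."""

    CLOUD = 1
    CLOUD_SHADOW = 2
    SNOW_ICE = 4
    INLAND_WATER = 8
    MIXED = 16
    OTHER_NOISE = 32

    #: bits that make a pixel unusable for water-colour retrieval
    BAD = CLOUD | CLOUD_SHADOW | SNOW_ICE | MIXED | OTHER_NOISE
    #: bits that make a pixel unobservable (cannot tell water from land)
    OBSCURED = CLOUD | CLOUD_SHADOW | SNOW_ICE


@dataclass(frozen=True)
class Affine:
    """Row/col -> world mapping: x = x0 + col*dx, y = y0 + row*dy.

    ``dy`` is normally negative (row index grows southward).  Coordinates of
    a pixel are taken at its centre (col + 0.5, row + 0.5).
    """

    x0: float
    dx: float
    y0: float
    dy: float

    def pixel_center(self, row, col):
        return self.x0 + (np.asarray(col) + 0.5) * self.dx, self.y0 + (
            np.asarray(row) + 0.5
        ) * self.dy

    def to_list(self):
        return [self.x0, self.dx, self.y0, self.dy]

    @classmethod
    def from_list(cls, vals):
        return cls(*map(float, vals))


#: default georeference: pixel size of 500 m expressed in degrees at the
#: equator, anchored at (0 E, 0 N); purely synthetic scenes use this.
DEG_PER_500M = 500.0 / 111320.0
DEFAULT_TRANSFORM = Affine(0.0, DEG_PER_500M, 0.0, -DEG_PER_500M)


@dataclass
class SceneStack:
    """One dated multiband reflectance raster with QA bitmask."""

    date: _dt.date
    bands: dict[str, np.ndarray]
    qa: np.ndarray
    transform: Affine = field(default_factory=lambda: DEFAULT_TRANSFORM)
    crs: str = "EPSG:4326"
    pixel_size_m: float = 500.0

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()} | {self.qa.shape}
        if len(shapes) != 1:
            raise ValueError("all bands and QA must share one shape")
        self.qa = np.asarray(self.qa, dtype=np.uint16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.qa.shape

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(
                f"band {name!r} not present; available: {sorted(self.bands)}"
            ) from None

    def pixel_area_km2(self) -> float:
        return (self.pixel_size_m / 1000.0) ** 2

    def with_bands(self, bands: dict[str, np.ndarray]) -> "SceneStack":
        return SceneStack(
            date=self.date,
            bands=bands,
            qa=self.qa.copy(),
            transform=self.transform,
            crs=self.crs,
            pixel_size_m=self.pixel_size_m,
        )


def write_scene(scene: SceneStack, path: str | Path) -> Path:
    """Write a scene as a multiband TIFF (float32 bands + uint16 QA page)."""
    path = Path(path)
    meta = {
        "date": scene.date.isoformat(),
        "band_names": scene.band_names,
        "transform": scene.transform.to_list(),
        "crs": scene.crs,
        "pixel_size_m": scene.pixel_size_m,
    }
    stack = np.stack([scene.bands[n].astype(np.float32) for n in scene.band_names])
    with tifffile.TiffWriter(path) as tw:
        tw.write(stack, description=json.dumps(meta))
        tw.write(scene.qa.astype(np.uint16))
    return path


def read_scene(path: str | Path) -> SceneStack:
    """Read a scene written by :func:`write_scene`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        meta = json.loads(tf.pages[0].description)
        stack = tf.series[0].asarray().astype(np.float64)
        qa = tf.series[1].asarray().astype(np.uint16)
    names = meta["band_names"]
    if "qa" in names:
        raise ValueError("'qa' is a reserved band name")
    bands = {name: stack[i] for i, name in enumerate(names)}
    return SceneStack(
        date=_dt.date.fromisoformat(meta["date"]),
        bands=bands,
        qa=qa,
        transform=Affine.from_list(meta["transform"]),
        crs=meta.get("crs", "EPSG:4326"),
        pixel_size_m=float(meta.get("pixel_size_m", 500.0)),
    )


def write_mask(mask: np.ndarray, path: str | Path, transform: Affine | None = None,
               crs: str = "EPSG:4326") -> Path:
    """Write a boolean or small-integer mask as a single-band TIFF."""
    path = Path(path)
    meta = {"transform": (transform or DEFAULT_TRANSFORM).to_list(), "crs": crs}
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8),
                     description=json.dumps(meta))
    return path


def read_mask(path: str | Path) -> tuple[np.ndarray, Affine]:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        meta = json.loads(tf.pages[0].description)
        arr = tf.asarray()
    return arr, Affine.from_list(meta["transform"])
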