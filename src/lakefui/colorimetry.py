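"""CIE-colorimetry Forel-Ule Index (FUI) retrieval.

Corrected red/green/blue reflectances are mapped to CIE tristimulus values
with a fixed linear transform, normalised to chromaticity coordinates, and
converted to a hue angle around the white point (1/3, 1/3).  A polynomial
deviation term compensates the hue bias introduced by discrete satellite
band positions, and the corrected angle is classified against a 21-class
look-up table spanning dark blue (1) to yellowish-brown (21).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RGB_TO_XYZ",
    "DELTA_COEFFS",
    "FUILookupTable",
    "load_lut",
    "rgb_to_xyz",
    "xyz_to_xy",
    "hue_angle",
    "hue_angle_prime",
    "delta_correction",
    "classify_fui",
    "fui_image",
    "FUI_NODATA",
]

#: Linear RGB -> XYZ conversion matrix (rows X, Y, Z; columns R, G, B).
RGB_TO_XYZ = np.array(
    [
        [2.7689, 1.7517, 1.1302],
        [1.00, 4.5907, 0.0601],
        [0.00, 0.0565, 5.5943],
    ]
)

#: Hue-deviation polynomial coefficients in a = alpha/100, highest power first.
DELTA_COEFFS = (-1.8185, 87.01, -486.65, 1004.93, -844.55, 220.28)

#: Integer nodata code for FUI rasters (classes are 1..21).
FUI_NODATA = 0

_WHITE = 1.0 / 3.0


@dataclass(frozen=True)
class FUILookupTable:
    """The 21 Forel-Ule classes with chromaticity coordinates and hue angles.

    ``alpha`` is measured anticlockwise from the positive x-axis;
    ``alpha_prime`` is the legacy clockwise convention starting from the
    negative y-branch.  For every record ``alpha + alpha_prime == 270``.
    """

    fui: np.ndarray
    x: np.ndarray
    y: np.ndarray
    alpha: np.ndarray
    alpha_prime: np.ndarray

    def __post_init__(self) -> None:
        if len(self.fui) != 21 or list(self.fui) != list(range(1, 22)):
            raise ValueError("look-up table must hold classes 1..21 in order")
        if not np.all(np.diff(self.alpha) < 0):
            raise ValueError("alpha must decrease strictly with class index")
        if not np.all(np.diff(self.alpha_prime) > 0):
            raise ValueError("alpha_prime must increase strictly with class index")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fui": self.fui,
                "x": self.x,
                "y": self.y,
                "alpha": self.alpha,
                "alpha_prime": self.alpha_prime,
            }
        )


def load_lut() -> FUILookupTable:
    """Load the packaged 21-class look-up table."""
    with importlib.resources.files("lakefui.data").joinpath("fui_lut.csv").open() as fh:
        df = pd.read_csv(fh)
    return FUILookupTable(
        fui=df["fui"].to_numpy(dtype=int),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        alpha=df["alpha"].to_numpy(dtype=float),
        alpha_prime=df["alpha_prime"].to_numpy(dtype=float),
    )


def rgb_to_xyz(r, g, b):
    """Convert red/green/blue reflectances to CIE tristimulus (X, Y, Z).

    Accepts scalars or arrays (broadcast elementwise).  Raises ``ValueError``
    for scalar all-zero input, whose chromaticity is undefined.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    if r.ndim == 0 and g.ndim == 0 and b.ndim == 0:
        if r == 0 and g == 0 and b == 0:
            raise ValueError("all-zero RGB input: chromaticity undefined")
    m = RGB_TO_XYZ
    x = m[0, 0] * r + m[0, 1] * g + m[0, 2] * b
    y = m[1, 0] * r + m[1, 1] * g + m[1, 2] * b
    z = m[2, 0] * r + m[2, 1] * g + m[2, 2] * b
    return x, y, z


def xyz_to_xy(x_tri, y_tri, z_tri):
    """Normalise tristimulus values to chromaticity coordinates (x, y)."""
    x_tri = np.asarray(x_tri, dtype=float)
    y_tri = np.asarray(y_tri, dtype=float)
    z_tri = np.asarray(z_tri, dtype=float)
    total = x_tri + y_tri + z_tri
    if np.ndim(total) == 0:
        if total <= 0:
            raise ValueError("X+Y+Z must be positive")
        return float(x_tri / total), float(y_tri / total)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(total > 0, x_tri / total, np.nan), np.where(
            total > 0, y_tri / total, np.nan
        )


def hue_angle(x, y):
    """Hue angle in degrees, anticlockwise from the positive x-axis.

    Computed as ``atan2(y - 1/3, x - 1/3)`` wrapped to [0, 2*pi) before
    conversion to degrees.  The white point itself has no hue.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0 and y.ndim == 0
    if scalar and abs(x - _WHITE) < 1e-12 and abs(y - _WHITE) < 1e-12:
        raise ValueError("hue undefined at the white point (1/3, 1/3)")
    alpha = np.degrees(np.mod(np.arctan2(y - _WHITE, x - _WHITE), 2.0 * np.pi))
    return float(alpha) if scalar else alpha


def hue_angle_prime(x, y):
    """Legacy hue angle: clockwise, ``atan2(x - 1/3, y - 1/3) + pi`` in degrees.

    Equals ``270 - hue_angle(x, y)`` (mod 360) on the colour locus; kept for
    cross-checking the older convention where the angle increases with class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0 and y.ndim == 0
    if scalar and abs(x - _WHITE) < 1e-12 and abs(y - _WHITE) < 1e-12:
        raise ValueError("hue undefined at the white point (1/3, 1/3)")
    alpha_p = np.degrees(
        np.mod(np.arctan2(x - _WHITE, y - _WHITE) + np.pi, 2.0 * np.pi)
    )
    return float(alpha_p) if scalar else alpha_p


def delta_correction(alpha):
    """Band-setting deviation: returns ``(delta, alpha + delta)`` in degrees."""
    alpha = np.asarray(alpha, dtype=float)
    a = alpha / 100.0
    delta = np.polyval(DELTA_COEFFS, a)
    corrected = alpha + delta
    if alpha.ndim == 0:
        return float(delta), float(corrected)
    return delta, corrected


def classify_fui(alpha_corrected, lut: FUILookupTable | None = None):
    """Classify a (corrected) hue angle to the nearest look-up-table class.

    Angles above the class-1 angle map to 1 and below the class-21 angle to
    21; ties go to the lower class index.  Non-finite input yields the
    nodata code for arrays and raises for scalars.
    """
    if lut is None:
        lut = _default_lut()
    alpha_corrected = np.asarray(alpha_corrected, dtype=float)
    scalar = alpha_corrected.ndim == 0
    if scalar and not np.isfinite(alpha_corrected):
        raise ValueError("non-finite hue angle")
    a = np.atleast_1d(alpha_corrected)
    # |a - alpha_k| with argmin returning the first (lower) class on ties
    dist = np.abs(a[..., None] - lut.alpha[None, :])
    cls = np.argmin(dist, axis=-1) + 1
    cls = np.where(a > lut.alpha[0], 1, cls)
    cls = np.where(a < lut.alpha[-1], 21, cls)
    cls = np.where(np.isfinite(a), cls, FUI_NODATA).astype(np.int16)
    return int(cls[0]) if scalar else cls.reshape(alpha_corrected.shape)


_LUT_CACHE: FUILookupTable | None = None


def _default_lut() -> FUILookupTable:
    global _LUT_CACHE
    if _LUT_CACHE is None:
        _LUT_CACHE = load_lut()
    return _LUT_CACHE


def fui_image(
    scene,
    mask: np.ndarray,
    lut: FUILookupTable | None = None,
    *,
    apply_delta: bool = True,
    band_names: tuple[str, str, str] = ("red", "green", "blue"),
) -> np.ndarray:
    """Per-pixel FUI classification of a corrected scene inside ``mask``.

    Pixels outside the mask, with non-positive tristimulus sum, or with a
    non-finite band value carry :data:`FUI_NODATA`.  ``apply_delta`` selects
    whether the band-setting deviation correction is applied before
    classification (it should be for satellite-band colours, not for
    true-colour chromaticities).
    """
    if lut is None:
        lut = _default_lut()
    red, green, blue = (scene.band(name) for name in band_names)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != red.shape:
        raise ValueError("mask shape does not match scene bands")
    out = np.full(red.shape, FUI_NODATA, dtype=np.int16)
    if not mask.any():
        return out
    r = red[mask]
    g = green[mask]
    b = blue[mask]
    xt, yt, zt = rgb_to_xyz(r, g, b)
    total = xt + yt + zt
    ok = np.isfinite(total) & (total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cx = np.where(ok, xt / np.where(ok, total, 1.0), np.nan)
        cy = np.where(ok, yt / np.where(ok, total, 1.0), np.nan)
    at_white = ok & np.isclose(cx, _WHITE) & np.isclose(cy, _WHITE)
    alpha = hue_angle(cx, cy)
    if apply_delta:
        _, alpha = delta_correction(alpha)
    cls = classify_fui(alpha, lut)
    cls = np.where(ok & ~at_white, cls, FUI_NODATA).astype(np.int16)
    out[mask] = cls
    return out
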