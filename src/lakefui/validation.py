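"""Matchup construction and agreement statistics.

Satellite classes are paired with classes derived from in situ reflectance
spectra (band-resampled with a rectangular response) at the nearest pixel
within a +/- 1 day window; agreement is summarised with the mean relative
difference (percent), root-mean-square error, and the product-moment
correlation for cross-dataset comparison.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import colorimetry as cm

__all__ = [
    "MatchupRecord",
    "MODIS_BAND_WINDOWS",
    "mrd",
    "rmse",
    "pearson_r",
    "resample_spectrum_to_bands",
    "classify_spectrum",
    "build_matchups",
]

#: nominal visible band windows (nm); rectangular spectral response
MODIS_BAND_WINDOWS = {
    "red": (620.0, 670.0),
    "green": (545.0, 565.0),
    "blue": (459.0, 479.0),
}


@dataclass
class MatchupRecord:
    lake_id: str
    site_lon: float
    site_lat: float
    sample_date: _dt.date
    fui_insitu: int
    fui_satellite: int
    time_gap_days: int


def mrd(estimated, measured) -> float:
    """Mean absolute relative difference, in percent.

    Not symmetric: the denominator is the measured value.
    """
    est = np.asarray(estimated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if est.shape != mea.shape or est.size == 0:
        raise ValueError("sequences must be non-empty and equal-length")
    if np.any(mea == 0):
        raise ValueError("measured values must be non-zero")
    return float(np.mean(np.abs(est - mea) / np.abs(mea)) * 100.0)


def rmse(estimated, measured) -> float:
    """Root-mean-square difference (n denominator)."""
    est = np.asarray(estimated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if est.shape != mea.shape or est.size == 0:
        raise ValueError("sequences must be non-empty and equal-length")
    return float(np.sqrt(np.mean((est - mea) ** 2)))


def pearson_r(series_a, series_b) -> float:
    """Product-moment correlation of paired series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need at least 3 paired points")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(stats.pearsonr(a, b).statistic)


def resample_spectrum_to_bands(
    wavelengths,
    reflectance,
    band_windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Average a reflectance spectrum over nominal band windows.

    Rectangular response: the unweighted mean of samples with wavelength
    inside each window (inclusive).  A window reaching outside the spectrum
    support, containing no samples, or containing NaN is an error.
    """
    if band_windows is None:
        band_windows = MODIS_BAND_WINDOWS
    wl = np.asarray(wavelengths, dtype=float)
    refl = np.asarray(reflectance, dtype=float)
    if wl.shape != refl.shape:
        raise ValueError("wavelength and reflectance arrays differ in shape")
    out = {}
    for name, (lo, hi) in band_windows.items():
        if lo < wl.min() or hi > wl.max():
            raise ValueError(f"band window {name} [{lo}, {hi}] outside spectrum "
                             f"support [{wl.min()}, {wl.max()}]")
        sel = (wl >= lo) & (wl <= hi)
        if not sel.any():
            raise ValueError(f"no spectral samples inside band window {name}")
        if np.isnan(refl[sel]).any():
            raise ValueError(f"NaN reflectance inside band window {name}")
        out[name] = float(refl[sel].mean())
    return out


def classify_spectrum(
    wavelengths,
    reflectance,
    *,
    apply_delta: bool = False,
    band_windows: dict[str, tuple[float, float]] | None = None,
) -> int:
    """In situ spectrum -> FUI class.

    By default the band-setting deviation correction is skipped: it models
    the bias of satellite band positions, not of band-resampled true
    colour.
    """
    bands = resample_spectrum_to_bands(wavelengths, reflectance, band_windows)
    x_t, y_t, z_t = cm.rgb_to_xyz(bands["red"], bands["green"], bands["blue"])
    x, y = cm.xyz_to_xy(x_t, y_t, z_t)
    alpha = cm.hue_angle(x, y)
    if apply_delta:
        _, alpha = cm.delta_correction(alpha)
    return cm.classify_fui(alpha)


def build_matchups(
    sites,
    fui_rasters: dict[_dt.date, np.ndarray],
    transform,
    *,
    lake_id: str = "",
    max_gap_days: int = 1,
    nodata: int = cm.FUI_NODATA,
    apply_delta_insitu: bool = False,
    log: list[str] | None = None,
) -> list[MatchupRecord]:
    """Pair in situ sites with the nearest pixel of the nearest-date raster.

    ``sites`` is an iterable of ``(lon, lat, date, wavelengths,
    reflectance)``.  The pixel is chosen by planar distance in the raster
    grid; the date by smallest absolute gap within ``max_gap_days``
    (inclusive), ties toward the earlier date.  Sites with no date in the
    window or a nodata pixel are dropped with a logged reason.
    """
    records = []
    dates = sorted(fui_rasters)
    for site in sites:
        lon, lat, when, wl, refl = site
        gaps = [(abs((d - when).days), d) for d in dates]
        gaps = [(g, d) for g, d in gaps if g <= max_gap_days]
        if not gaps:
            if log is not None:
                log.append(f"site ({lon:.4f}, {lat:.4f}) {when}: no raster "
                           f"within {max_gap_days} day(s)")
            continue
        gaps.sort(key=lambda t: (t[0], t[1]))
        gap, chosen = gaps[0]
        raster = fui_rasters[chosen]
        col = (lon - transform.x0) / transform.dx - 0.5
        row = (lat - transform.y0) / transform.dy - 0.5
        r = int(np.clip(round(row), 0, raster.shape[0] - 1))
        c = int(np.clip(round(col), 0, raster.shape[1] - 1))
        sat = int(raster[r, c])
        if sat == nodata:
            if log is not None:
                log.append(f"site ({lon:.4f}, {lat:.4f}) {when}: nearest pixel "
                           f"has no valid retrieval on {chosen}")
            continue
        insitu = classify_spectrum(wl, refl, apply_delta=apply_delta_insitu)
        records.append(
            MatchupRecord(
                lake_id=lake_id, site_lon=lon, site_lat=lat, sample_date=when,
                fui_insitu=insitu, fui_satellite=sat,
                time_gap_days=int((chosen - when).days),
            )
        )
    return records
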