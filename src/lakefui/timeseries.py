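"""Quality-controlled monthly and yearly per-lake FUI series.

Composite-level FUI rasters are reduced to monthly rasters with a per-pixel
temporal outlier trim (mu +/- 3 sigma), then to per-lake monthly means with
a spatial trim (mu +/- 1.5 sigma) and a >30% coverage requirement.  Lakes
failing the valid-months rules are dropped, interior gaps are linearly
interpolated, and yearly means and ordinary-least-squares trends complete
the record.  Both filters are single pass and use the sample standard
deviation (n-1 denominator); with fewer than three values no trimming is
attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MonthlyRecord",
    "YearlyRecord",
    "temporal_filter",
    "monthly_composite",
    "spatial_mean",
    "apply_validity_rules",
    "fill_gaps",
    "yearly_mean",
    "annual_trend",
    "MAY_OCT",
]

K_TEMPORAL = 3.0
K_SPATIAL = 1.5
MIN_COVERAGE = 0.30
MIN_MONTHS_NONFREEZING = 6
MIN_MONTHS_FREEZING = 3
MAY_OCT = range(5, 11)


@dataclass
class MonthlyRecord:
    lake_id: str
    year: int
    month: int
    fui_raw: float | None
    fui_filled: float | None = None
    n_pixels_used: int = 0
    coverage: float = 0.0
    filled: bool = False
    valid: bool = False

    @property
    def month_index(self) -> int:
        return self.year * 12 + (self.month - 1)

    @property
    def value(self) -> float | None:
        return self.fui_raw if self.fui_raw is not None else self.fui_filled


@dataclass
class YearlyRecord:
    lake_id: str
    year: int
    fui_yearly: float
    n_months: int


def _sigma_trim(values: np.ndarray, k: float) -> np.ndarray:
    """Single-pass mu +/- k*sigma trim; no-op for n < 3 or zero spread."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        return values
    mu = values.mean()
    sigma = values.std(ddof=1)
    if sigma == 0:
        return values
    keep = values[np.abs(values - mu) <= k * sigma]
    if keep.size < values.size / 2:
        warnings.warn(
            f"sigma trim removed more than half the sample "
            f"({values.size - keep.size} of {values.size})"
        )
    return keep


def temporal_filter(values, k: float = K_TEMPORAL) -> np.ndarray:
    """Trim per-pixel composite values within one time window."""
    return _sigma_trim(values, k)


def stack_temporal_filter(stack: np.ndarray, k: float = K_TEMPORAL) -> np.ndarray:
    """Vectorised mu +/- k*sigma trim along axis 0 of a (dates, ...) stack.

    NaN marks missing observations; trimmed values become NaN.  Columns
    with fewer than three finite values are left untouched.  With a single
    pass and only a handful of samples the trim cannot fire (the largest
    possible z-score is (n-1)/sqrt(n)), so callers wanting outlier
    rejection should pass the full record per pixel, not one month.
    """
    stack = np.asarray(stack, dtype=float)
    n = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(stack, axis=0)
        sigma = np.nanstd(stack, axis=0, ddof=1)
    out = stack.copy()
    trim = (
        (np.abs(stack - mu) > k * sigma)
        & (n >= 3)
        & (sigma > 0)
        & np.isfinite(stack)
    )
    out[trim] = np.nan
    return out


def spatial_filter(values, k: float = K_SPATIAL) -> np.ndarray:
    """Trim in-mask pixel values of one monthly raster."""
    return _sigma_trim(values, k)


def monthly_composite(
    fui_rasters: list[np.ndarray],
    mask: np.ndarray,
    k: float = K_TEMPORAL,
    nodata: int = 0,
) -> np.ndarray:
    """Per-pixel temporal trim + mean over one month's composites.

    Input rasters hold integer classes with ``nodata`` where unobserved;
    the result is a float raster with NaN where no composite observed the
    pixel.
    """
    if not fui_rasters:
        raise ValueError("no rasters in month")
    mask = np.asarray(mask, dtype=bool)
    stack = np.stack([np.asarray(r, dtype=float) for r in fui_rasters])
    stack[stack == nodata] = np.nan
    out = np.full(mask.shape, np.nan)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        vals = stack[:, r, c]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        kept = temporal_filter(vals, k)
        if kept.size:
            out[r, c] = kept.mean()
    return out


def spatial_mean(
    monthly_raster: np.ndarray,
    mask: np.ndarray,
    lake_id: str,
    year: int,
    month: int,
    k: float = K_SPATIAL,
    min_coverage: float = MIN_COVERAGE,
) -> MonthlyRecord:
    """Reduce a monthly raster to one lake-month record.

    Coverage is the observed fraction of normal-mask pixels; at or below
    ``min_coverage`` the record is invalid and carries no value.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty normal water mask")
    vals = np.asarray(monthly_raster, dtype=float)[mask]
    observed = np.isfinite(vals)
    coverage = float(observed.mean())
    if coverage <= min_coverage:
        return MonthlyRecord(lake_id, year, month, fui_raw=None,
                             coverage=coverage, valid=False)
    kept = spatial_filter(vals[observed], k)
    return MonthlyRecord(
        lake_id, year, month,
        fui_raw=float(kept.mean()),
        n_pixels_used=int(kept.size),
        coverage=coverage,
        valid=True,
    )


def apply_validity_rules(
    series: list[MonthlyRecord],
    freezing: bool,
    min_months_nonfreezing: int = MIN_MONTHS_NONFREEZING,
    min_months_freezing: int = MIN_MONTHS_FREEZING,
    drop_lake_on_any_bad_year: bool = True,
) -> tuple[list[MonthlyRecord], bool]:
    """Freezing-window restriction and valid-months-per-year rule.

    Freezing lakes keep only May-October records.  With
    ``drop_lake_on_any_bad_year`` (the default) the lake is excluded from
    the dataset if any calendar year in its record span fails its minimum;
    otherwise only the failing years are removed.
    """
    if freezing:
        series = [r for r in series if r.month in MAY_OCT]
    if not series:
        return [], False
    minimum = min_months_freezing if freezing else min_months_nonfreezing
    years = range(min(r.year for r in series), max(r.year for r in series) + 1)
    valid_per_year = {
        y: sum(1 for r in series if r.year == y and r.valid) for y in years
    }
    bad_years = {y for y, n in valid_per_year.items() if n < minimum}
    if not bad_years:
        return series, True
    if drop_lake_on_any_bad_year:
        return series, False
    return [r for r in series if r.year not in bad_years], True


def fill_gaps(series: list[MonthlyRecord]) -> list[MonthlyRecord]:
    """Linear interpolation of interior missing months, in place.

    Filling runs along the month index between the nearest valid
    neighbours.  For records restricted to the May-October window the
    interpolation is confined within each year's window (the ice season is
    not bridged).  Leading and trailing gaps stay missing.  Idempotent;
    never alters non-missing values.
    """
    series = sorted(series, key=lambda r: r.month_index)
    if not series:
        return series
    may_oct_only = all(r.month in MAY_OCT for r in series)
    groups: dict[int | None, list[MonthlyRecord]] = {}
    if may_oct_only:
        for r in series:  # freezing lake: fill within each year's window
            groups.setdefault(r.year, []).append(r)
    else:
        groups[None] = series
    for recs in groups.values():
        idx = np.array([r.month_index for r in recs])
        vals = np.array(
            [r.value if r.value is not None else np.nan for r in recs]
        )
        known = np.isfinite(vals)
        if known.sum() < 2:
            continue
        first, last = np.flatnonzero(known)[[0, -1]]
        for i, r in enumerate(recs):
            if known[i] or not (first < i < last):
                continue
            r.fui_filled = float(
                np.interp(idx[i], idx[known], vals[known])
            )
            r.filled = True
    return series


def yearly_mean(series: list[MonthlyRecord], year: int,
                lake_id: str | None = None) -> YearlyRecord | None:
    """Arithmetic mean of a year's monthly values (raw and filled alike)."""
    vals = [r.value for r in series if r.year == year and r.value is not None]
    if not vals:
        return None
    lid = lake_id if lake_id is not None else (series[0].lake_id if series else "")
    return YearlyRecord(lid, year, float(np.mean(vals)), len(vals))


def annual_trend(yearly: dict[int, float]) -> tuple[float, float]:
    """OLS slope of yearly FUI on calendar year and its two-sided p-value."""
    if len(yearly) < 3:
        raise ValueError("need at least 3 years for a trend")
    years = np.array(sorted(yearly))
    vals = np.array([yearly[y] for y in years], dtype=float)
    if np.allclose(vals, vals[0]):
        return 0.0, 1.0
    res = stats.linregress(years, vals)
    return float(res.slope), float(res.pvalue)
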