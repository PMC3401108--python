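"""NDVI time-series smoothing and pixel-to-location aggregation.

Satellite NDVI composites carry characteristic artifacts: cloud, snow and
atmospheric interference produce sudden spikes, water pixels and persistent
snow produce negative values. The cleaning rules implemented here:

1. **Winter zeroing** (northern locations only): negative values falling in
   a designated winter window (at most the Nov–May periods) are snow, not
   anomalies, and are replaced with exactly 0 before any other step.
2. **Negative-run removal**: a pixel with three or more consecutive
   strictly negative values is dropped (likely water or unusable data).
3. **Spike correction**: a jump of more than 0.25 NDVI units followed by a
   rapid return to the pre-jump level is an anomaly. A single-step spike is
   replaced by the mean of its flanks; two consecutive anomalous steps are
   replaced by linear interpolation between the flanks (weights 2/3–1/3 and
   1/3–2/3).
4. **Aggregation**: per-time-step mean over retained pixels; a location
   keeping fewer than 50% of its pixels is excluded.

The fixed order is winter zeroing -> negative-run removal -> spike
correction -> aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPIKE_THRESHOLD = 0.25
MIN_PIXEL_FRACTION = 0.5
NEGATIVE_RUN_LENGTH = 3

#: Default winter window for bi-monthly (24 periods/year) data: the six
#: months November through April (periods 20..23 and 0..7; period 0 = first
#: half of January), the maximal fixed window inside the permitted Nov-May
#: span. Callers with other cadences must supply their own window.
DEFAULT_WINTER_WINDOW_24 = frozenset(range(20, 24)) | frozenset(range(0, 8))


@dataclass(frozen=True)
class PixelSeries:
    """One pixel's NDVI values on a (year, within-year period) grid."""

    location_id: str
    pixel_id: str
    values: np.ndarray  # shape (n_years, periods_per_year)
    removed: bool = False
    removal_reason: str = "none"  # "none" | "water" | "negative_run"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("values must be a non-empty (years x periods) array")
        object.__setattr__(self, "values", v)

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def periods_per_year(self) -> int:
        return self.values.shape[1]

    def flat(self) -> np.ndarray:
        """The series in time order as a 1-D array."""
        return self.values.ravel()


@dataclass(frozen=True)
class LocationSeries:
    """Pixel-averaged NDVI series for one location."""

    location_id: str
    values: np.ndarray  # (n_years, periods_per_year), NaN where no pixel contributes
    n_pixels_retained: int
    n_pixels_initial: int
    retained: bool

    def flat(self) -> np.ndarray:
        return self.values.ravel()

    def across_years_mean(self) -> np.ndarray:
        """Mean annual profile (per within-year period), a descriptive output."""
        return np.nanmean(self.values, axis=0)


def _validate_winter_window(window: frozenset | set, periods_per_year: int) -> None:
    # Six months = half the annual cycle; the window may not exceed it.
    max_len = periods_per_year // 2 + periods_per_year % 2
    if len(window) > max_len:
        raise ValueError(
            f"winter window of {len(window)} periods exceeds 6 months "
            f"({max_len} of {periods_per_year} periods)"
        )
    if any(p < 0 or p >= periods_per_year for p in window):
        raise ValueError("winter window contains out-of-range period indices")


def zero_winter_negatives(series: PixelSeries, winter_window) -> PixelSeries:
    """Replace negative values in the winter window with exactly 0.

    Intended for northern locations where winter snow cover makes negative
    NDVI expected rather than anomalous. Other values are untouched.
    """
    window = frozenset(winter_window)
    _validate_winter_window(window, series.periods_per_year)
    v = series.values.copy()
    cols = sorted(window)
    block = v[:, cols]
    block[block < 0] = 0.0
    v[:, cols] = block
    return replace(series, values=v)


def flag_negative_runs(series: PixelSeries, run_length: int = NEGATIVE_RUN_LENGTH) -> PixelSeries:
    """Mark the pixel removed if it has >= ``run_length`` consecutive negative values."""
    if series.removed:
        raise ValueError("series already removed")
    flat = series.flat()
    if flat.size == 0:
        raise ValueError("empty series")
    neg = flat < 0
    run = 0
    for is_neg in neg:
        run = run + 1 if is_neg else 0
        if run >= run_length:
            return replace(series, removed=True, removal_reason="negative_run")
    return series


def correct_spikes(
    series: PixelSeries, threshold: float = SPIKE_THRESHOLD
) -> tuple[PixelSeries, list[int]]:
    """Despike a pixel series; returns the corrected series and the indices fixed.

    A single-observation anomaly at t satisfies |v_t - v_{t-1}| > threshold
    with a rapid return |v_{t+1} - v_{t-1}| <= threshold, and is replaced by
    (v_{t-1} + v_{t+1})/2. Two consecutive anomalies at (t, t+1), both
    deviating > threshold from the flanks v_{t-1}, v_{t+2} with
    |v_{t+2} - v_{t-1}| <= threshold, are replaced by linear interpolation
    between the flanks. One left-to-right pass; corrected values are used as
    the left flank for subsequent positions.
    """
    v = series.flat().copy()
    n = v.size
    if n < 3:
        logger.warning(
            "correct_spikes: series %s/%s shorter than 3, returned unchanged",
            series.location_id,
            series.pixel_id,
        )
        return series, []

    fixed: list[int] = []
    t = 1
    while t < n - 1:
        jump = abs(v[t] - v[t - 1])
        if jump > threshold and abs(v[t + 1] - v[t - 1]) <= threshold:
            v[t] = 0.5 * (v[t - 1] + v[t + 1])
            fixed.append(t)
            t += 2
            continue
        if (
            t < n - 2
            and jump > threshold
            and abs(v[t + 1] - v[t + 2]) > threshold
            and abs(v[t + 2] - v[t - 1]) <= threshold
        ):
            lo, hi = v[t - 1], v[t + 2]
            v[t] = (2.0 * lo + hi) / 3.0
            v[t + 1] = (lo + 2.0 * hi) / 3.0
            fixed.extend([t, t + 1])
            t += 3
            continue
        t += 1

    out = replace(series, values=v.reshape(series.values.shape))
    return out, fixed


def aggregate_location(
    pixels: list[PixelSeries], min_fraction: float = MIN_PIXEL_FRACTION
) -> LocationSeries:
    """Average retained pixels per time step; exclude the location if fewer
    than ``min_fraction`` of its pixels survive (exactly the fraction is kept)."""
    if not pixels:
        raise ValueError("no pixels supplied")
    location_id = pixels[0].location_id
    retained_px = [p for p in pixels if not p.removed]
    n_init = len(pixels)
    n_kept = len(retained_px)
    retained = n_kept / n_init >= min_fraction and n_kept > 0
    if retained_px:
        stack = np.stack([p.values for p in retained_px])
        values = stack.mean(axis=0)
    else:
        values = np.full_like(pixels[0].values, np.nan)
    return LocationSeries(
        location_id=location_id,
        values=values,
        n_pixels_retained=n_kept,
        n_pixels_initial=n_init,
        retained=retained,
    )


@dataclass
class QcRecord:
    location_id: str
    n_pixels_initial: int
    n_pixels_retained: int
    n_spikes_corrected: int
    retained: bool


def smooth_location(
    pixels: list[PixelSeries],
    northern: bool = False,
    winter_window=None,
    threshold: float = SPIKE_THRESHOLD,
    min_fraction: float = MIN_PIXEL_FRACTION,
) -> tuple[LocationSeries, QcRecord]:
    """Run the full cleaning pipeline for one location's pixels.

    Order: winter zeroing (northern only) -> negative-run removal -> spike
    correction -> aggregation.
    """
    if northern and winter_window is None:
        if pixels[0].periods_per_year != 24:
            raise ValueError("winter_window required for non-bi-monthly cadence")
        winter_window = DEFAULT_WINTER_WINDOW_24

    n_spikes = 0
    processed: list[PixelSeries] = []
    for px in pixels:
        if px.removed:  # e.g. pre-flagged water pixels
            processed.append(px)
            continue
        if northern:
            px = zero_winter_negatives(px, winter_window)
        px = flag_negative_runs(px)
        if px.removed:
            processed.append(px)
            continue
        px, fixed = correct_spikes(px, threshold=threshold)
        n_spikes += len(fixed)
        processed.append(px)

    loc = aggregate_location(processed, min_fraction=min_fraction)
    qc = QcRecord(
        location_id=loc.location_id,
        n_pixels_initial=loc.n_pixels_initial,
        n_pixels_retained=loc.n_pixels_retained,
        n_spikes_corrected=n_spikes,
        retained=loc.retained,
    )
    return loc, qc


# ---------------------------------------------------------------------------
# Long-format CSV interchange
# ---------------------------------------------------------------------------

def pixels_to_frame(pixels: list[PixelSeries]) -> pd.DataFrame:
    """Long format: location_id, pixel_id, year, period, ndvi."""
    frames = []
    for px in pixels:
        ny, pp = px.values.shape
        years, periods = np.meshgrid(np.arange(ny), np.arange(pp), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "location_id": px.location_id,
                    "pixel_id": px.pixel_id,
                    "year": years.ravel(),
                    "period": periods.ravel(),
                    "ndvi": px.values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_pixels(df: pd.DataFrame) -> list[PixelSeries]:
    """Inverse of :func:`pixels_to_frame`; requires a complete grid per pixel."""
    out = []
    for (loc, pix), g in df.groupby(["location_id", "pixel_id"], sort=True):
        g = g.sort_values(["year", "period"])
        years = g["year"].to_numpy()
        periods = g["period"].to_numpy()
        ny = int(years.max()) - int(years.min()) + 1
        pp = int(periods.max()) + 1
        if len(g) != ny * pp:
            raise ValueError(f"pixel {loc}/{pix} has an incomplete (year, period) grid")
        values = g["ndvi"].to_numpy().reshape(ny, pp)
        out.append(PixelSeries(location_id=str(loc), pixel_id=str(pix), values=values))
    return out


def smooth_frame(
    df: pd.DataFrame,
    northern_locations: set[str] | None = None,
    winter_window=None,
    threshold: float = SPIKE_THRESHOLD,
    min_fraction: float = MIN_PIXEL_FRACTION,
) -> tuple[dict[str, LocationSeries], pd.DataFrame]:
    """Clean a long-format NDVI frame; returns location series and a QC report."""
    northern_locations = northern_locations or set()
    pixels = frame_to_pixels(df)
    by_loc: dict[str, list[PixelSeries]] = {}
    for px in pixels:
        by_loc.setdefault(px.location_id, []).append(px)

    locations: dict[str, LocationSeries] = {}
    qc_rows = []
    for loc_id in sorted(by_loc):
        loc, qc = smooth_location(
            by_loc[loc_id],
            northern=loc_id in northern_locations,
            winter_window=winter_window,
            threshold=threshold,
            min_fraction=min_fraction,
        )
        locations[loc_id] = loc
        qc_rows.append(vars(qc))
    return locations, pd.DataFrame(qc_rows)
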