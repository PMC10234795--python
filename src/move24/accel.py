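"""Time-use estimates and directly measured acceleration metrics.

Cut-points for youth non-dominant-wrist ENMO split waking time into
sedentary (< 48 mg), light (48-201 mg), moderate (201-707 mg) and
vigorous (>= 707 mg) activity; epochs inside the detected nightly sleep
period count as sleep.  Volume and intensity of the activity profile are
summarised by the average acceleration and the intensity gradient (slope
of ln(time) on ln(intensity) over 25-mg bins).  Daily values are averaged
as a weighted week (5:2 weekday:weekend).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochSeries, is_weekend

PARTS = ("sleep", "st", "lpa", "mpa", "vpa")


@dataclass(frozen=True)
class CutPoints:
    """ENMO thresholds (mg).  Boundary epochs join the higher category."""
    st_upper: float = 48.0
    mpa_lower: float = 201.0
    vpa_lower: float = 707.0

    def __post_init__(self):
        if not (0 < self.st_upper < self.mpa_lower < self.vpa_lower):
            raise ValueError("cut-points must satisfy 0 < ST < MPA < VPA")


def screen_valid_days(series: EpochSeries, min_weekdays: int = 3,
                      min_weekend: int = 1) -> tuple[list, bool]:
    """Complete calendar days and whether wear criteria are met.

    Returns (retained days, valid) where valid requires at least
    ``min_weekdays`` complete weekdays and ``min_weekend`` complete
    weekend days.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    days = series.complete_days()
    n_we = sum(is_weekend(d) for d in days)
    n_wd = len(days) - n_we
    return days, (n_wd >= min_weekdays and n_we >= min_weekend)


def weighted_week(daily: dict) -> float:
    """(5 * weekday mean + 2 * weekend mean) / 7 over per-day values.

    ``daily`` maps dates to values.  Requires at least one weekday and one
    weekend value.
    """
    wd = [v for d, v in daily.items() if not is_weekend(d) and np.isfinite(v)]
    we = [v for d, v in daily.items() if is_weekend(d) and np.isfinite(v)]
    if not wd or not we:
        raise ValueError("weighted week requires both weekday and weekend values")
    return (5.0 * float(np.mean(wd)) + 2.0 * float(np.mean(we))) / 7.0


def _sleep_mask(series: EpochSeries, sleep_windows) -> np.ndarray:
    """Boolean mask of epochs inside any sleep-period window."""
    ts = series.timestamps
    mask = np.zeros(len(series), dtype=bool)
    windows = sorted(sleep_windows, key=lambda w: w.onset)
    for a, b in zip(windows, windows[1:]):
        if b.onset < a.offset:
            raise ValueError("overlapping sleep windows")
    for w in windows:
        mask |= (ts >= w.onset) & (ts < w.offset)
    return mask


def classify_time_use(series: EpochSeries, cutpoints: CutPoints = CutPoints(),
                      sleep_windows=(), days=None) -> pd.DataFrame:
    """Per-day 5-part time use (minutes), closed to 1440.

    Epochs inside a sleep window count as sleep, attributed to the day of
    that window's onset (so a night spanning midnight is not split).
    Waking epochs are binned by ENMO against the cut-points; the boundary
    value joins the higher intensity.  Raw daily minutes are then closed
    to 1440.
    """
    if days is None:
        days = series.complete_days()
    days = sorted(days)
    epoch_min = series.epoch_seconds / 60.0
    windows = sorted(sleep_windows, key=lambda w: w.onset)
    smask = _sleep_mask(series, windows)
    enmo = series.enmo
    day_idx = series.day_index()

    sleep_by_day = {d: 0.0 for d in days}
    for w in windows:
        onset_day = pd.Timestamp(w.onset).date()
        if onset_day in sleep_by_day:
            sleep_by_day[onset_day] += (w.offset - w.onset).total_seconds() / 60.0

    rows = []
    for d in days:
        sel = day_idx == np.datetime64(d, "D")
        wake = enmo[sel & ~smask]
        st = float(np.sum(wake < cutpoints.st_upper)) * epoch_min
        lpa = float(np.sum((wake >= cutpoints.st_upper)
                           & (wake < cutpoints.mpa_lower))) * epoch_min
        mpa = float(np.sum((wake >= cutpoints.mpa_lower)
                           & (wake < cutpoints.vpa_lower))) * epoch_min
        vpa = float(np.sum(wake >= cutpoints.vpa_lower)) * epoch_min
        # sleep keeps the full onset-day window; waking parts are rescaled
        # to fill the remaining minutes (absorbs the midnight-crossing
        # mismatch between this day's morning tail and the next's)
        slp = min(sleep_by_day[d], 1440.0)
        waking = np.array([st, lpa, mpa, vpa])
        target = 1440.0 - slp
        if waking.sum() > 0:
            waking = waking * (target / waking.sum())
        closed = np.concatenate([[slp], waking])
        rows.append({"date": d, **dict(zip(PARTS, closed))})
    return pd.DataFrame(rows).set_index("date")


def average_time_use(per_day: pd.DataFrame) -> pd.Series:
    """Weighted-week average of per-day compositions, re-closed to 1440."""
    avg = {p: weighted_week(per_day[p].to_dict()) for p in PARTS}
    s = pd.Series(avg)
    return s * (1440.0 / s.sum())


def average_acceleration(series: EpochSeries, days=None) -> float:
    """Weighted-week mean ENMO (mg) over retained complete days."""
    if days is None:
        days = series.complete_days()
    if not days:
        raise ValueError("no retained days")
    daily = {d: float(series.enmo[series.day_slice(d)].mean()) for d in days}
    return weighted_week(daily)


def _ig_fit(minutes: np.ndarray, mids: np.ndarray):
    keep = minutes > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-empty intensity bins")
    x, y = np.log(mids[keep]), np.log(minutes[keep])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / sst if sst > 0 else np.nan
    return float(slope), float(intercept), float(r2)


def intensity_gradient_day(enmo: np.ndarray, epoch_seconds: float,
                           bin_width: float = 25.0):
    """(slope, intercept, r^2) of ln(minutes) on ln(bin midpoint) for one day.

    Bins are [0,25), [25,50), ... mg with midpoints (lower+upper)/2;
    zero-minute bins are dropped (ln 0 undefined).
    """
    enmo = np.asarray(enmo, dtype=float)
    top = max(float(enmo.max()), bin_width)
    edges = np.arange(0.0, np.ceil(top / bin_width) * bin_width + bin_width,
                      bin_width)
    counts, _ = np.histogram(enmo, bins=edges)
    minutes = counts * (epoch_seconds / 60.0)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return _ig_fit(minutes, mids)


def intensity_gradient(series: EpochSeries, bin_width: float = 25.0,
                       days=None) -> tuple[float, float, float]:
    """Weighted-week averaged daily intensity-gradient fit."""
    if days is None:
        days = series.complete_days()
    if not days:
        raise ValueError("no retained days")
    per_day = {}
    for d in days:
        sl = series.day_slice(d)
        per_day[d] = intensity_gradient_day(series.enmo[sl],
                                            series.epoch_seconds, bin_width)
    slope = weighted_week({d: v[0] for d, v in per_day.items()})
    intercept = weighted_week({d: v[1] for d, v in per_day.items()})
    r2 = weighted_week({d: v[2] for d, v in per_day.items()})
    return slope, intercept, r2
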