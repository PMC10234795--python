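"""Sleep-period detection from wrist z-angle dynamics.

The nightly sleep period time (SPT) window is found from sustained low
variability of the z-angle (the axis perpendicular to the skin): absolute
successive differences of the per-epoch z-angle are smoothed with a 5-min
rolling median; epochs below a data-driven threshold (15 x the night's
10th percentile of the smoothed values, capped) form candidate rest
segments; segments of >= 30 min separated by < 60 min are merged and the
longest merged block is the SPT window.  Above-threshold intervals inside
the window are wake bouts (awakenings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSeries
from .accel import weighted_week


@dataclass
class SleepWindow:
    """Detected sleep period for one night."""
    onset: pd.Timestamp
    offset: pd.Timestamp
    wake_bouts: list = field(default_factory=list)   # list of (start, end)
    implausible: bool = False

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("sleep window offset must follow onset")

    @property
    def window_minutes(self) -> float:
        return (self.offset - self.onset).total_seconds() / 60.0

    @property
    def wake_minutes(self) -> float:
        return sum((b - a).total_seconds() / 60.0 for a, b in self.wake_bouts)

    @property
    def sleep_minutes(self) -> float:
        return self.window_minutes - self.wake_minutes

    @property
    def efficiency(self) -> float:
        return 100.0 * self.sleep_minutes / self.window_minutes

    @property
    def onset_hours(self) -> float:
        """Clock time of onset in decimal hours; times after midnight are
        reported as > 24 (00:30 -> 24.5) so nights average sensibly."""
        t = pd.Timestamp(self.onset)
        h = t.hour + t.minute / 60.0 + t.second / 3600.0
        return h + 24.0 if h < 12.0 else h


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs (stop exclusive)."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    stops = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_sleep_period(series: EpochSeries, night_start,
                        smooth_minutes: float = 5.0,
                        threshold_factor: float = 15.0,
                        threshold_cap_deg: float = 5.0,
                        min_segment_minutes: float = 30.0,
                        merge_gap_minutes: float = 60.0,
                        min_bout_minutes: float = 1.0,
                        implausible_hours: float = 12.0) -> SleepWindow | None:
    """Detect the SPT window in the noon-to-noon night starting at
    ``night_start`` (a date; the night runs 12:00 that day to 12:00 next).

    Returns None when no candidate rest segment of ``min_segment_minutes``
    exists.  Wake bouts shorter than ``min_bout_minutes`` are ignored
    (epoch-noise debounce); windows longer than ``implausible_hours`` are
    flagged rather than truncated.
    """
    t0 = pd.Timestamp(night_start).normalize() + pd.Timedelta(hours=12)
    t1 = t0 + pd.Timedelta(hours=24)
    ts = series.timestamps
    sel = (ts >= t0) & (ts < t1)
    if sel.sum() < 2:
        return None
    z = series.z_angle[sel]
    ts = ts[sel]
    step = series.epoch_seconds

    dz = np.abs(np.diff(z, prepend=z[0]))
    win = max(1, int(round(smooth_minutes * 60.0 / step)))
    rolled = pd.Series(dz).rolling(win, center=True, min_periods=1).median().to_numpy()

    thresh = min(threshold_factor * np.percentile(rolled, 10), threshold_cap_deg)
    below = rolled <= thresh
    min_len = int(round(min_segment_minutes * 60.0 / step))
    segments = [(a, b) for a, b in _runs(below) if b - a >= min_len]
    if not segments:
        return None

    # merge segments separated by short gaps
    gap_len = int(round(merge_gap_minutes * 60.0 / step))
    merged = [list(segments[0])]
    for a, b in segments[1:]:
        if a - merged[-1][1] < gap_len:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    a, b = max(merged, key=lambda ab: ab[1] - ab[0])

    bout_len = int(round(min_bout_minutes * 60.0 / step))
    bouts = []
    for ba, bb in _runs(~below[a:b]):
        if bb - ba >= bout_len:
            bouts.append((ts[a + ba], ts[a + bb - 1] + pd.Timedelta(seconds=step)))
    offset = ts[b - 1] + pd.Timedelta(seconds=step)
    w = SleepWindow(onset=ts[a], offset=offset, wake_bouts=bouts)
    if w.window_minutes > implausible_hours * 60.0:
        w.implausible = True
    return w


def detect_all_nights(series: EpochSeries, **kwargs) -> list[SleepWindow]:
    """SPT windows for every noon-to-noon night fully inside the series."""
    ts = series.timestamps
    first = ts[0].normalize()
    if ts[0] > first + pd.Timedelta(hours=12):
        first += pd.Timedelta(days=1)
    windows = []
    night = first
    while night + pd.Timedelta(hours=36) <= ts[-1] + pd.Timedelta(seconds=series.epoch_seconds):
        w = detect_sleep_period(series, night, **kwargs)
        if w is not None:
            windows.append(w)
        night += pd.Timedelta(days=1)
    return windows


def summarize_sleep(windows) -> pd.Series:
    """Weighted-week per-night sleep summary.

    duration = window minus wake-bout minutes (time asleep); efficiency =
    100 x duration / window length ("time in bed" operationalised as the
    detected SPT window); onset in decimal hours (after-midnight onsets
    > 24); awakenings = wake-bout count.  Night type is taken from the
    onset day.
    """
    windows = [w for w in windows if not w.implausible]
    if not windows:
        raise ValueError("no plausible sleep windows")

    def agg(values):
        daily = {pd.Timestamp(w.onset).date(): v for w, v in zip(windows, values)}
        try:
            return weighted_week(daily)
        except ValueError:            # only one day-type present
            return float(np.mean(list(daily.values())))

    return pd.Series({
        "sleep_duration_min": agg([w.sleep_minutes for w in windows]),
        "sleep_window_min": agg([w.window_minutes for w in windows]),
        "sleep_efficiency_pct": agg([w.efficiency for w in windows]),
        "sleep_onset_hours": agg([w.onset_hours for w in windows]),
        "n_awakenings": agg([float(len(w.wake_bouts)) for w in windows]),
        "n_nights": float(len(windows)),
    })
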