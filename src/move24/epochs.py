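"""Epoch-level wrist-accelerometer series.

The package starts from calibrated epoch data: per participant, a
uniformly spaced series of ENMO (Euclidean Norm Minus One, in
milligravitational units, mg) and the z-angle of the wrist (degrees),
typically at 5-s epochs.  Upstream raw-signal processing (calibration,
non-wear handling) is assumed done.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EpochSeries:
    """Uniformly sampled ENMO / z-angle series for one participant."""

    participant_id: str
    start: pd.Timestamp
    epoch_seconds: int
    enmo: np.ndarray      # mg, >= 0
    z_angle: np.ndarray   # degrees, [-90, 90]

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.enmo = np.asarray(self.enmo, dtype=float)
        self.z_angle = np.asarray(self.z_angle, dtype=float)
        if self.enmo.shape != self.z_angle.shape or self.enmo.ndim != 1:
            raise ValueError("enmo and z_angle must be 1-d arrays of equal length")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if np.any(self.enmo < 0):
            raise ValueError("negative ENMO value")

    def __len__(self) -> int:
        return len(self.enmo)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_seconds, unit="s")

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_seconds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp": self.timestamps,
            "enmo_mg": self.enmo,
            "z_angle_deg": self.z_angle,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, participant_id: str) -> "EpochSeries":
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        if len(ts) < 2:
            raise ValueError("series requires at least two epochs")
        deltas = np.diff(ts.view("int64"))
        if np.any(deltas <= 0):
            row = int(np.argmax(deltas <= 0)) + 1
            raise ValueError(f"non-increasing timestamp at row {row}")
        step = deltas[0]
        if np.any(deltas != step):
            row = int(np.argmax(deltas != step)) + 1
            raise ValueError(f"non-uniform epoch spacing at row {row}")
        return cls(participant_id, ts[0], int(step // 10**9),
                   df["enmo_mg"].to_numpy(dtype=float),
                   df["z_angle_deg"].to_numpy(dtype=float))

    # -- day bookkeeping ----------------------------------------------------

    def day_index(self) -> np.ndarray:
        """Calendar date (as numpy datetime64[D]) of each epoch."""
        return self.timestamps.values.astype("datetime64[D]")

    def complete_days(self) -> list:
        """Dates covered by a full midnight-to-midnight block of epochs."""
        days = self.day_index()
        uniq, counts = np.unique(days, return_counts=True)
        return [pd.Timestamp(d).date() for d, c in zip(uniq, counts)
                if c == self.epochs_per_day]

    def day_slice(self, date) -> slice:
        """Index slice of the epochs falling on the given calendar date.

        Uniform spacing makes this arithmetic: no timestamp scan needed.
        """
        d0 = pd.Timestamp(date).normalize()
        off = (d0 - self.start).total_seconds()
        i0 = max(int(np.ceil(off / self.epoch_seconds)), 0)
        i1 = min(int(np.ceil((off + 86400) / self.epoch_seconds)), len(self))
        if i0 >= i1:
            raise KeyError(f"no epochs on {date}")
        return slice(i0, i1)


def is_weekend(date) -> bool:
    return pd.Timestamp(date).weekday() >= 5
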