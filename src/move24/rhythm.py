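"""24-hour rest-activity rhythm metrics.

Parametric: the anti-logistic extended cosinor, fitted by nonlinear least
squares to minute-level log(ENMO mg + 1),

    Y(t) = min + A * G(cos(2*pi*(t - phi)/24)),
    G(r) = exp(beta*(r - alpha)) / (1 + exp(beta*(r - alpha))),

with minimum level ``min``, amplitude ``A`` (peak minus minimum),
acrophase ``phi`` (clock time of the peak, decimal hours), and shape
parameters ``alpha`` (width of the peak, in [-1, 1]) and ``beta``
(steepness of the rise, > 0).  The mesor is reported as min + A/2.

Non-parametric: inter-daily stability (IS), intra-daily variability (IV)
computed on hourly means, and the most-active-10-h (M10) / least-active-
5-h (L5) means of the average 24-h minute profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .epochs import EpochSeries


def minute_log_profile(series: EpochSeries, days=None):
    """(hours-of-series, log(ENMO+1)) at 1-min resolution over complete days."""
    if days is None:
        days = series.complete_days()
    if not days:
        raise ValueError("no complete days")
    per_min = 60 // series.epoch_seconds
    segs_t, segs_y = [], []
    for k, d in enumerate(sorted(days)):
        sl = series.day_slice(d)
        e = series.enmo[sl].reshape(1440, per_min).mean(axis=1)
        segs_y.append(np.log(e + 1.0))
        segs_t.append(np.arange(1440) / 60.0 + 24.0 * k)
    return np.concatenate(segs_t), np.concatenate(segs_y)


@dataclass
class CosinorResults:
    """Extended-cosinor fit; activity scale is log(mg + 1)."""
    minimum_level: float
    amplitude: float
    acrophase: float          # decimal hours in [0, 24)
    alpha: float
    beta: float
    fit_rss: float
    converged: bool
    flat: bool = False        # amplitude indistinguishable from noise

    @property
    def mesor(self) -> float:
        return self.minimum_level + self.amplitude / 2.0

    def predict(self, t_hours) -> np.ndarray:
        r = np.cos(2.0 * np.pi * (np.asarray(t_hours, float) - self.acrophase) / 24.0)
        return self.minimum_level + self.amplitude * expit(self.beta * (r - self.alpha))

    def summary(self) -> str:
        return (f"Extended cosinor (log mg+1): min={self.minimum_level:.3f} "
                f"amp={self.amplitude:.3f} mesor={self.mesor:.3f} "
                f"acrophase={self.acrophase:.2f} h alpha={self.alpha:.3f} "
                f"beta={self.beta:.3f} rss={self.fit_rss:.2f} "
                f"converged={self.converged}" + (" [flat]" if self.flat else ""))


class ExtendedCosinorModel:
    """Anti-logistic extended cosinor fitted to an epoch series.

    The series is aggregated to 1-min means of log(ENMO + 1) over its
    complete days before fitting.  ``fit`` multi-starts the acrophase at
    0, 6, 12 and 18 h and returns the best-RSS solution.
    """

    def __init__(self, series: EpochSeries | None = None, days=None,
                 t_hours=None, y=None):
        if series is not None:
            self.t, self.y = minute_log_profile(series, days)
        else:
            self.t = np.asarray(t_hours, dtype=float)
            self.y = np.asarray(y, dtype=float)
        if len(self.t) < 3 * 1440 and series is not None:
            raise ValueError("cosinor fit requires at least 3 complete days")

    @staticmethod
    def _model(p, t):
        mn, a, phi, al, be = p
        r = np.cos(2.0 * np.pi * (t - phi) / 24.0)
        return mn + a * expit(be * (r - al))

    def fit(self, starts=(0.0, 6.0, 12.0, 18.0)) -> CosinorResults:
        t, y = self.t, self.y
        lo = np.array([-np.inf, 0.0, -24.0, -1.0, 1e-3])
        hi = np.array([np.inf, np.inf, 48.0, 1.0, 50.0])
        y_min, y_ptp = float(y.min()), float(np.ptp(y))
        best, best_rss, converged = None, np.inf, False
        for phi0 in starts:
            p0 = np.array([y_min, max(y_ptp, 1e-3), phi0, 0.0, 2.0])
            try:
                sol = least_squares(lambda p: self._model(p, t) - y, p0,
                                    bounds=(lo, hi), method="trf")
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if rss < best_rss:
                best, best_rss, converged = sol.x, rss, bool(sol.success)
        if best is None:
            raise RuntimeError("cosinor optimisation failed from every start")
        mn, a, phi, al, be = best
        phi = float(phi % 24.0)
        # flat-signal degeneracy: the rhythm explains almost none of the
        # variance, so amplitude sits in the noise and the acrophase is
        # unreliable
        sst = float(np.sum((y - y.mean()) ** 2))
        flat = bool(a < 1e-6 or sst <= 0 or (sst - best_rss) / sst < 0.05)
        return CosinorResults(float(mn), float(a), phi, float(al), float(be),
                              best_rss, converged, flat=flat)


def nonparametric_rhythm(series: EpochSeries, days=None,
                         bin_minutes: int = 60) -> pd.Series:
    """IS, IV and M10/L5 summary of the rest-activity profile.

    IS and IV use means over ``bin_minutes`` bins (hourly by default):
      IS = [n * sum_h (xbar_h - xbar)^2] / [p * sum_i (x_i - xbar)^2]
      IV = [n * sum_{i>=2} (x_i - x_{i-1})^2] / [(n-1) * sum_i (x_i - xbar)^2]
    with p bins per day and n total bins.  M10/L5 are the max/min circular
    rolling means of the average 24-h minute-level ENMO profile over
    600/300-min windows, with window start clock times.
    """
    if days is None:
        days = series.complete_days()
    days = sorted(days)
    if len(days) < 3:
        raise ValueError("non-parametric rhythm metrics require >= 3 complete days")
    per_bin = bin_minutes * 60 // series.epoch_seconds
    p = 1440 // bin_minutes
    day_mat = []
    minute_mat = []
    per_min = 60 // series.epoch_seconds
    for d in days:
        sl = series.day_slice(d)
        e = series.enmo[sl]
        day_mat.append(e.reshape(p, per_bin).mean(axis=1))
        minute_mat.append(e.reshape(1440, per_min).mean(axis=1))
    x = np.asarray(day_mat)               # days x p bins
    xi = x.ravel()                        # chronological bins
    n = xi.size
    xbar = xi.mean()
    sst = np.sum((xi - xbar) ** 2)
    flagged = sst <= 0

    if flagged:
        is_ = np.nan
        iv = np.nan
    else:
        hourly_means = x.mean(axis=0)
        is_ = (n * np.sum((hourly_means - xbar) ** 2)) / (p * sst)
        iv = (n * np.sum(np.diff(xi) ** 2)) / ((n - 1) * sst)

    profile = np.asarray(minute_mat).mean(axis=0)
    m10, m10_onset = _extreme_window(profile, 600, np.argmax)
    l5, l5_onset = _extreme_window(profile, 300, np.argmin)
    return pd.Series({
        "is": float(is_), "iv": float(iv),
        "m10": float(m10), "l5": float(l5),
        "m10_onset": float(m10_onset), "l5_onset": float(l5_onset),
        "rhythm_flagged": bool(flagged),
    })


def _extreme_window(profile: np.ndarray, width: int, pick):
    """Mean and start hour of the extreme circular rolling window."""
    ext = np.concatenate([profile, profile[:width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    means = (csum[width:] - csum[:-width]) / width
    means = means[:1440]
    i = int(pick(means))
    return means[i], i / 60.0
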