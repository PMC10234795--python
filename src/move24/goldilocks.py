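"""Optimal time-use composition ("Goldilocks Day") grid search.

Enumerates every feasible composition of sleep, ST, LPA, MPA and VPA on
a 10-minute lattice within per-behaviour ranges (mean +/- 3 SD of the
observed compositions, intersected with the observed support), predicts
the mental-health outcome for each composition from a fitted
compositional regression with covariates held at reference values, and
summarises the most favourable 5% of predictions (the optimal time-use
zone) by its compositional mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coda import geometric_mean_composition, replace_zeros

PARTS = ("sleep", "st", "lpa", "mpa", "vpa")
DAY_MINUTES = 1440


@dataclass
class GridSpec:
    """Lattice of candidate daily compositions."""
    ranges: dict                      # behaviour -> (min, max) minutes
    step: int = 10
    total: int = DAY_MINUTES
    parts: tuple = PARTS

    def __post_init__(self):
        if self.total % self.step != 0:
            raise ValueError("step must divide the daily total")
        fixed = {}
        for p in self.parts:
            lo, hi = self.ranges[p]
            lo = max(0.0, lo)
            hi = min(float(self.total), hi)
            if lo > hi:
                raise ValueError(f"empty range for {p}")
            fixed[p] = (float(lo), float(hi))
        self.ranges = fixed


def truncation_ranges(compositions, k: float = 3.0, step: int = 10,
                      clip_to_observed: bool = True, parts=PARTS) -> GridSpec:
    """Per-behaviour [mean - k*SD, mean + k*SD] ranges on the minutes
    scale, optionally intersected with the observed min/max, clipped to
    [0, 1440] and rounded outward to the grid step."""
    x = np.atleast_2d(np.asarray(compositions, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("truncation ranges require at least 2 compositions")
    mean, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
    if np.any(sd == 0) and k > 0:
        raise ValueError("degenerate (zero-SD) behaviour")
    ranges = {}
    for j, p in enumerate(parts):
        lo, hi = mean[j] - k * sd[j], mean[j] + k * sd[j]
        if clip_to_observed:
            lo, hi = max(lo, x[:, j].min()), min(hi, x[:, j].max())
        lo = math.floor(max(lo, 0.0) / step) * step
        hi = math.ceil(min(hi, DAY_MINUTES) / step) * step
        if k == 0:
            lo = hi = round(mean[j] / step) * step
        ranges[p] = (lo, hi)
    return GridSpec(ranges=ranges, step=step)


def enumerate_grid(spec: GridSpec) -> np.ndarray:
    """All compositions on the lattice summing exactly to ``spec.total``,
    in lexicographic order of the parts.  Vectorised over the last part:
    loops the first D-2 parts and solves the last from the total."""
    step, total = spec.step, spec.total
    los = [math.ceil(spec.ranges[p][0] / step) for p in spec.parts]
    his = [math.floor(spec.ranges[p][1] / step) for p in spec.parts]
    t = total // step
    rows = []
    d = len(spec.parts)

    def rec(prefix, remaining, depth):
        if depth == d - 2:
            a_lo, a_hi = los[d - 2], his[d - 2]
            b_lo, b_hi = los[d - 1], his[d - 1]
            lo = max(a_lo, remaining - b_hi)
            hi = min(a_hi, remaining - b_lo)
            if lo > hi:
                return
            a = np.arange(lo, hi + 1)
            b = remaining - a
            block = np.empty((a.size, d), dtype=np.int64)
            block[:, :d - 2] = prefix
            block[:, d - 2] = a
            block[:, d - 1] = b
            rows.append(block)
            return
        # prune: remaining must stay attainable by the parts left
        tail_lo = sum(los[depth + 1:])
        tail_hi = sum(his[depth + 1:])
        for v in range(los[depth], his[depth] + 1):
            r = remaining - v
            if r < tail_lo or r > tail_hi:
                continue
            rec(prefix + [v], r, depth + 1)

    rec([], t, 0)
    if not rows:
        raise ValueError("no feasible composition on the grid")
    return np.concatenate(rows, axis=0) * step


@dataclass
class GoldilocksResult:
    """Optimal time-use zone summary for one outcome."""
    outcome: str
    spec: GridSpec
    grid: np.ndarray                  # grid_size x 5 minutes
    predictions: np.ndarray
    zone_fraction: float
    direction: str
    zone_mask: np.ndarray
    optimal_composition: np.ndarray   # compositional mean of the zone
    sample_mean_composition: np.ndarray | None = None

    @property
    def grid_size(self) -> int:
        return int(self.grid.shape[0])

    @property
    def zone_size(self) -> int:
        return int(self.zone_mask.sum())

    def summary(self) -> str:
        opt = ", ".join(f"{p}={v:.0f}" for p, v in zip(PARTS, self.optimal_composition))
        lines = [f"Goldilocks search: {self.outcome}",
                 f"grid size = {self.grid_size}, zone = {self.zone_size} "
                 f"({100 * self.zone_fraction:.0f}% most favourable, {self.direction})",
                 f"optimal composition (min/day): {opt}"]
        if self.sample_mean_composition is not None:
            sm = ", ".join(f"{p}={v:.0f}"
                           for p, v in zip(PARTS, self.sample_mean_composition))
            lines.append(f"sample mean composition:      {sm}")
        return "\n".join(lines)


def predict_grid(grid: np.ndarray, results, covariates=None,
                 zero_delta=0.5) -> np.ndarray:
    """Predicted outcome for each grid composition from a fitted
    compositional model, covariates fixed at reference values (sample
    means / proportions by default).  Grid rows containing zeros are
    routed through multiplicative zero replacement before the ILR."""
    return results.predict(grid, covariates=covariates, zero_delta=zero_delta)


def optimal_zone(grid: np.ndarray, predictions, outcome: str = "outcome",
                 spec: GridSpec | None = None, fraction: float = 0.05,
                 direction: str = "lower", sample_mean=None,
                 zero_delta=0.5) -> GoldilocksResult:
    """Most favourable ``fraction`` of predictions and its compositional
    mean.  ``direction`` "lower" treats small predictions as favourable
    (SDQ difficulties); ties at the zone boundary are included, so the
    zone may slightly exceed the nominal fraction."""
    pred = np.asarray(predictions, dtype=float)
    if pred.size == 0:
        raise ValueError("no predictions")
    k = math.ceil(fraction * pred.size)
    srt = np.sort(pred)
    cut = srt[k - 1] if direction == "lower" else srt[-k]
    mask = pred <= cut if direction == "lower" else pred >= cut
    zone = np.asarray(grid, dtype=float)[mask]
    zone_pos = np.atleast_2d(replace_zeros(zone, delta=zero_delta)) \
        if np.any(zone == 0) else zone
    opt = geometric_mean_composition(zone_pos)
    return GoldilocksResult(outcome=outcome, spec=spec, grid=np.asarray(grid),
                            predictions=pred, zone_fraction=fraction,
                            direction=direction, zone_mask=mask,
                            optimal_composition=opt,
                            sample_mean_composition=None if sample_mean is None
                            else np.asarray(sample_mean, dtype=float))


def goldilocks_search(compositions, results, outcome: str = "outcome",
                      k: float = 3.0, step: int = 10, fraction: float = 0.05,
                      direction: str = "lower", covariates=None) -> GoldilocksResult:
    """End-to-end search: truncation ranges -> grid -> predictions -> zone."""
    comps = np.atleast_2d(np.asarray(compositions, dtype=float))
    spec = truncation_ranges(comps, k=k, step=step)
    grid = enumerate_grid(spec)
    pred = predict_grid(grid, results, covariates=covariates)
    res = optimal_zone(grid, pred, outcome=outcome, spec=spec,
                       fraction=fraction, direction=direction)
    res.sample_mean_composition = geometric_mean_composition(
        np.atleast_2d(replace_zeros(comps)))
    return res


def radar_data(optimal, sample_mean, sleep_guideline: float = 540.0,
               mvpa_guideline: float = 60.0) -> pd.DataFrame:
    """Plot-ready table comparing the optimal and sample-mean compositions
    against guideline markers (minimum sleep 540 min/night; minimum MVPA
    60 min/day averaged over the week, MVPA = MPA + VPA)."""
    opt = np.asarray(optimal, dtype=float)
    sm = np.asarray(sample_mean, dtype=float)
    rows = []
    for j, p in enumerate(PARTS):
        rows.append({"behaviour": p, "optimal_min": opt[j],
                     "sample_mean_min": sm[j],
                     "guideline_min": sleep_guideline if p == "sleep" else np.nan})
    rows.append({"behaviour": "mvpa", "optimal_min": opt[3] + opt[4],
                 "sample_mean_min": sm[3] + sm[4],
                 "guideline_min": mvpa_guideline})
    return pd.DataFrame(rows).set_index("behaviour")
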