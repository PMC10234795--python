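"""Self-validation experiments on synthetic cohorts with known truth.

Each function generates data with the synthetic module (or a
regression-level equivalent), runs the corresponding analysis stage, and
returns summary statistics of how well the planted quantities are
recovered.  They are used by the acceptance tests and the acceptance
script; problem sizes are chosen so the whole battery runs on a single
CPU in a few minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .accel import _ig_fit, average_acceleration
from .coda import (PARTS, CompositionMentalHealthModel, close, pivot_ilr,
                   replace_zeros)
from .cohort import metric_association
from .epochs import EpochSeries
from .goldilocks import GridSpec, enumerate_grid, optimal_zone
from .rhythm import ExtendedCosinorModel, nonparametric_rhythm
from .sleep import detect_all_nights, summarize_sleep
from .synthetic import SimulationConfig, simulate_cohort


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# rhythm metrics
# ---------------------------------------------------------------------------

def cosinor_recovery(n_participants: int = 200, seed: int = 0,
                     noise_sd: float = 0.1) -> dict:
    """Fit the extended cosinor to pure-rhythm synthetic participants and
    compare against the planted parameters."""
    cfg = SimulationConfig.pure_rhythm(
        n_participants=n_participants, seed=_sub_seed(seed, 1),
        noise_sd=noise_sd)
    cohort = simulate_cohort(cfg)
    truth = cohort.ground_truth["participants"]
    acro_err, amp_rel_err = [], []
    for i, series in enumerate(cohort.series):
        fit = ExtendedCosinorModel(series).fit()
        planted = truth.iloc[i]
        d = abs(fit.acrophase - planted["acrophase"]) % 24.0
        acro_err.append(min(d, 24.0 - d))
        amp_rel_err.append(abs(fit.amplitude - planted["amplitude"])
                           / planted["amplitude"])
    return {
        "median_acrophase_error_h": float(np.median(acro_err)),
        "median_amplitude_rel_error_pct": float(100 * np.median(amp_rel_err)),
        "n": n_participants,
    }


def is_identical_days(seed: int = 0, n_days: int = 5) -> float:
    """IS of a series built by repeating one day exactly."""
    rng = np.random.default_rng(_sub_seed(seed, 2))
    day = rng.uniform(0.0, 100.0, 86400 // 5)
    series = EpochSeries("IS01", pd.Timestamp("2022-09-05"), 5,
                         np.tile(day, n_days), np.zeros(n_days * len(day)))
    return float(nonparametric_rhythm(series)["is"])


def iv_white_noise(n_days: int = 1000, seed: int = 0) -> float:
    """IV of iid Gaussian hourly activity over many days (expected 2)."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    hourly = np.clip(rng.normal(50.0, 10.0, n_days * 24), 0.0, None)
    enmo = np.repeat(hourly, 3600 // 60)   # 1-min epochs
    series = EpochSeries("IV01", pd.Timestamp("2022-09-05"), 60, enmo,
                         np.zeros_like(enmo))
    return float(nonparametric_rhythm(series)["iv"])


def m10_ge_l5(seed: int = 0, n_series: int = 20) -> bool:
    """M10 >= L5 over random multi-day profiles."""
    rng = np.random.default_rng(_sub_seed(seed, 4))
    ok = True
    for _ in range(n_series):
        enmo = np.abs(rng.normal(40.0, 20.0, 3 * 1440))
        s = EpochSeries("ML", pd.Timestamp("2022-09-05"), 60, enmo,
                        np.zeros_like(enmo))
        m = nonparametric_rhythm(s)
        ok &= bool(m["m10"] >= m["l5"])
    return ok


def intensity_gradient_power_law() -> float:
    """Slope of the intensity gradient on an exact power-law day:
    minutes per bin proportional to midpoint^-2 (expected -2)."""
    mids = np.arange(12.5, 25.0 * 16, 25.0)
    minutes = 2.0e5 * mids ** -2.0
    slope, _, _ = _ig_fit(minutes, mids)
    return float(slope)


# ---------------------------------------------------------------------------
# compositional regression
# ---------------------------------------------------------------------------

def ilr_invariance(seed: int = 0, n: int = 200) -> float:
    """Max absolute log-likelihood discrepancy across the five pivot
    bases fitted to one dataset (expected 0)."""
    rng = np.random.default_rng(_sub_seed(seed, 5))
    comps = close(np.exp(rng.normal(np.log([500, 520, 300, 70, 15]), 0.2,
                                    size=(n, 5))))
    df = pd.DataFrame(comps, columns=PARTS)
    df["school_id"] = [f"S{i % 8}" for i in range(n)]
    df["bmiz"] = rng.normal(0, 1, n)
    z1 = pivot_ilr(comps, "sleep")[:, 0]
    school_eff = rng.normal(0, 3.0, 8)[np.arange(n) % 8]
    df["y"] = 11 - 3.0 * z1 + school_eff + rng.normal(0, 4, n)
    res = CompositionMentalHealthModel.from_dataframe(
        df, "y", covariates=["bmiz"]).fit(stratify_on_sex=False)
    lls = np.array(list(res.loglik_by_pivot.values()))
    return float(np.ptp(lls))


def type_one_error(n_reps: int = 1000, n: int = 200, n_schools: int = 10,
                   seed: int = 0) -> dict:
    """Rejection rates at alpha = 0.05 under the null: the outcome is
    school effects + noise, independent of the composition and of the
    exposure."""
    rng = np.random.default_rng(_sub_seed(seed, 6))
    school = np.array([f"S{i % n_schools}" for i in range(n)])
    rej_comp, rej_assoc = 0, 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            comps = close(np.exp(rng.normal(np.log([500, 520, 300, 70, 15]),
                                            0.15, size=(n, 5))))
            cov = pd.DataFrame({"sex_girl": rng.integers(0, 2, n).astype(float),
                                "eimd_decile": rng.integers(1, 11, n).astype(float)})
            y = (rng.normal(0.0, 1.0, n_schools)[np.arange(n) % n_schools]
                 + rng.normal(0.0, 5.0, n) + 11.0)
            model = CompositionMentalHealthModel(comps, y, cov, school)
            if model.omnibus_test() < 0.05:
                rej_comp += 1
            df = cov.copy()
            df["exposure"] = rng.normal(0.0, 1.0, n)
            df["y"] = y
            df["school_id"] = school
            r = metric_association(df, "exposure", "y",
                                   covariates=["sex_girl", "eimd_decile"],
                                   stratify_on_sex=False)
            if r.p < 0.05:
                rej_assoc += 1
    return {"compositional_rejection_pct": 100.0 * rej_comp / n_reps,
            "association_rejection_pct": 100.0 * rej_assoc / n_reps,
            "n_reps": n_reps, "n": n}


def coefficient_recovery(n: int = 300, seed: int = 0) -> dict:
    """Fit the one-for-remaining model to a synthetic cohort's true
    compositions and compare the sleep- and ST-pivot coefficients with
    the planted values (sleep -6.0, ST +4.7)."""
    cfg = SimulationConfig(n_participants=n, n_schools=10,
                           seed=_sub_seed(seed, 7))
    cohort = simulate_cohort(cfg, generate_signal=False)
    truth = cohort.ground_truth
    gt = truth["participants"]
    df = pd.DataFrame(
        replace_zeros(gt[[f"true_{b}" for b in PARTS]].to_numpy(), delta=0.5),
        columns=PARTS)
    df["y"] = gt["sdq_total"].to_numpy(dtype=float)
    df["school_id"] = gt["school_id"].to_numpy()
    part = cohort.participants
    df["sex_girl"] = (part["sex"] == "girl").astype(float)
    df["age"] = part["age"].astype(float)
    df["eimd_decile"] = part["eimd_decile"].astype(float)
    df["bmiz"] = part["bmiz"].astype(float)
    res = CompositionMentalHealthModel.from_dataframe(
        df, "y", covariates=["sex_girl", "age", "eimd_decile", "bmiz"]).fit(
        stratify_on_sex=False)
    out = {"n": n, "omnibus_p": res.omnibus_p}
    for b in ("sleep", "st"):
        e = res.effects[b]
        out[f"beta_{b}"] = e.beta
        out[f"beta_{b}_ci_low"] = e.ci_low
        out[f"beta_{b}_ci_high"] = e.ci_high
        out[f"beta_{b}_truth"] = float(truth["pivot_betas"][b])
        out[f"beta_{b}_in_ci"] = bool(e.ci_low <= out[f"beta_{b}_truth"]
                                      <= e.ci_high)
    return out


def coefficient_recovery_coverage(n_reps: int = 5, n: int = 300,
                                  seed: int = 0) -> dict:
    """Repeat the coefficient-recovery experiment on independent cohorts
    and count how often each planted pivot coefficient falls inside its
    fitted 95% CI (a per-CI ~95%-probability event)."""
    hits = {"sleep": 0, "st": 0}
    for k in range(n_reps):
        r = coefficient_recovery(n=n, seed=_sub_seed(seed, 100 + k))
        for b in hits:
            hits[b] += int(r[f"beta_{b}_in_ci"])
    return {"sleep_in_ci": hits["sleep"], "st_in_ci": hits["st"],
            "n_reps": n_reps, "n": n}


# ---------------------------------------------------------------------------
# goldilocks
# ---------------------------------------------------------------------------

def goldilocks_recovery(step: int = 10) -> dict:
    """Plant a quadratic outcome surface with an interior optimum on the
    ILR scale and check the zone's compositional mean recovers it."""
    spec = GridSpec(ranges={"sleep": (420, 620), "st": (380, 620),
                            "lpa": (220, 420), "mpa": (30, 110),
                            "vpa": (10, 40)}, step=step)
    grid = enumerate_grid(spec)
    target = np.array([520.0, 500.0, 330.0, 70.0, 20.0])
    z = pivot_ilr(grid.astype(float), "sleep")
    zt = pivot_ilr(target, "sleep")
    pred = ((z - zt) ** 2).sum(axis=1)
    res = optimal_zone(grid, pred, fraction=0.05, spec=spec)
    off = np.abs(res.optimal_composition - target)
    return {"max_offset_min": float(off.max()), "grid_size": res.grid_size,
            "zone_size": res.zone_size, "step": step}


def grid_enumeration_oracle() -> dict:
    """Toy 3-part grid versus an exhaustive triple loop."""
    spec = GridSpec(ranges={"a": (10, 40), "b": (10, 40), "c": (10, 40)},
                    step=10, total=60, parts=("a", "b", "c"))
    grid = enumerate_grid(spec)
    brute = [(a, b, c) for a in range(10, 41, 10) for b in range(10, 41, 10)
             for c in range(10, 41, 10) if a + b + c == 60]
    return {"grid_count": int(len(grid)), "oracle_count": len(brute),
            "match": sorted(map(tuple, grid.tolist())) == sorted(brute)}


# ---------------------------------------------------------------------------
# full-pipeline cohort summary
# ---------------------------------------------------------------------------

def cohort_characteristics(n_participants: int = 24, seed: int = 0) -> dict:
    """Run the epoch-level measurement chain on a default synthetic
    cohort and summarise the characteristics the generator is calibrated
    to (average acceleration, sleep efficiency, SDQ clipping)."""
    cfg = SimulationConfig(n_participants=n_participants, n_schools=6,
                           seed=_sub_seed(seed, 8))
    cohort = simulate_cohort(cfg)
    avacc, eff = [], []
    for series in cohort.series:
        avacc.append(average_acceleration(series))
        eff.append(float(summarize_sleep(
            detect_all_nights(series))["sleep_efficiency_pct"]))
    return {"mean_avg_acceleration_mg": float(np.mean(avacc)),
            "mean_sleep_efficiency_pct": float(np.mean(eff)),
            "sdq_clipping_rate_pct":
                100.0 * float(cohort.ground_truth["clipping_rate"]),
            "n": n_participants}
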