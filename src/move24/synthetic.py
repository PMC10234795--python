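"""Synthetic school-clustered cohorts with known ground truth.

Emulates the statistical structure the analysis chain assumes: each
participant gets a multi-day 5-s epoch ENMO/z-angle series driven by an
anti-logistic extended cosinor on the log(mg + 1) scale, a planted
nocturnal sleep window expressed through near-constant z-angle (with
high-variability awakening bouts), planted moderate/vigorous activity
bouts placed around the acrophase, school-clustered covariates, and SDQ
outcomes drawn from a linear model on the true time-use composition's
ILR coordinates plus covariates and a school random intercept.

Higher SDQ scores mean worse mental health (more difficulties); the
outcome model's sign convention follows that.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .epochs import EpochSeries
from .accel import CutPoints
from .coda import clr_gradient_for_betas, pivot_beta_from_clr_gradient, replace_zeros

PARTS = ("sleep", "st", "lpa", "mpa", "vpa")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CosinorPopulation:
    """Population distribution of per-participant cosinor parameters
    (activity on the log(mg+1) scale, acrophase in decimal hours)."""
    minimum_mean: float = 0.3
    minimum_sd: float = 0.1
    amplitude_mean: float = 4.6
    amplitude_sd: float = 0.2
    # keeps every daytime plateau above the sedentary/light threshold, so
    # between-person light-activity time varies smoothly instead of
    # collapsing to zero for low-amplitude participants
    amplitude_range: tuple = (4.25, 5.1)
    acrophase_mean: float = 14.4
    acrophase_sd: float = 0.8
    alpha_mean: float = 0.0
    alpha_sd: float = 0.05
    beta_mean: float = 2.0
    beta_sd: float = 0.2


@dataclass
class SleepPopulation:
    """Planted sleep-window distribution (hours / minutes)."""
    onset_mean: float = 22.4       # decimal hours
    onset_sd: float = 0.5
    duration_mean: float = 530.0   # minutes
    duration_sd: float = 30.0
    night_onset_jitter_sd: float = 0.15   # hours, night-to-night
    n_awakenings_mean: float = 10.0       # Poisson, per night
    awakening_length_min: float = 8.0
    awakening_separation_min: float = 31.0  # keeps inter-bout sleep >= 30 min
    resting_z_jitter_sd: float = 0.3      # degrees


@dataclass
class ActivityPopulation:
    """Planted daily MPA/VPA bout minutes and their ENMO ranges (mg)."""
    mpa_minutes_mean: float = 65.0
    mpa_minutes_sd: float = 15.0
    vpa_minutes_mean: float = 12.0
    vpa_minutes_sd: float = 5.0
    day_to_day_sd: float = 0.1     # multiplicative day-level jitter
    mpa_enmo_range: tuple = (230.0, 500.0)
    vpa_enmo_range: tuple = (750.0, 1000.0)


@dataclass
class CovariatePopulation:
    """School-clustered covariates: sex, two age groups (9-10 and 12-13 y),
    area-deprivation decile (EIMD, 1-10) and BMI z-score."""
    p_girl: float = 0.6
    p_child: float = 0.615
    child_age_mean: float = 9.8
    child_age_sd: float = 0.4
    adolescent_age_mean: float = 13.1
    adolescent_age_sd: float = 0.3
    eimd_mean: float = 6.7
    eimd_sd: float = 2.9
    bmiz_mean: float = 0.48
    bmiz_sd: float = 1.22


@dataclass
class OutcomeModel:
    """Linear model generating SDQ total difficulties.

    The compositional effect is specified as first-pivot coefficients
    (behaviour vs the geometric mean of the rest); internally these map
    to a zero-sum clr gradient so all five pivot betas are implied at
    once.  Totals are clipped to [0, 40].
    """
    intercept: float = 15.6
    pivot_betas: dict = field(default_factory=lambda: {"sleep": -6.0, "st": 4.7})
    coef_sex_girl: float = -0.8
    coef_adolescent: float = -1.2
    coef_eimd: float = -0.2
    coef_bmiz: float = 0.3
    school_sd: float = 1.0
    residual_sd: float = 5.0


@dataclass
class SimulationConfig:
    n_participants: int = 200
    n_schools: int = 10
    n_days: int = 7
    epoch_seconds: int = 5
    start_monday: str = "2022-09-05"   # first complete (Mon) day
    noise_sd: float = 0.1              # log(mg+1) scale
    cosinor: CosinorPopulation = field(default_factory=CosinorPopulation)
    sleep: SleepPopulation = field(default_factory=SleepPopulation)
    activity: ActivityPopulation = field(default_factory=ActivityPopulation)
    covariates: CovariatePopulation = field(default_factory=CovariatePopulation)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0 <= self.sleep.onset_mean < 24:
            raise ValueError("sleep onset must be a clock hour in [0, 24)")
        if self.sleep.duration_mean >= 1440 or self.sleep.duration_mean <= 0:
            raise ValueError("sleep window must be shorter than 24 h")
        if self.n_days < 1 or self.n_participants < 1 or self.n_schools < 1:
            raise ValueError("counts must be positive")
        if 60 % self.epoch_seconds != 0:
            raise ValueError("epoch length must divide one minute")

    @classmethod
    def pure_rhythm(cls, **kwargs) -> "SimulationConfig":
        """Variant with no planted activity bouts or awakenings, so the
        ENMO signal is exactly the noisy anti-logistic cosinor process."""
        cfg = cls(**kwargs)
        cfg.activity.mpa_minutes_mean = 0.0
        cfg.activity.mpa_minutes_sd = 0.0
        cfg.activity.vpa_minutes_mean = 0.0
        cfg.activity.vpa_minutes_sd = 0.0
        cfg.sleep.n_awakenings_mean = 0.0
        return cfg


# ---------------------------------------------------------------------------
# per-participant planted parameters
# ---------------------------------------------------------------------------

def _draw_participant(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    c, s, a = cfg.cosinor, cfg.sleep, cfg.activity
    return {
        "minimum_level": rng.normal(c.minimum_mean, c.minimum_sd),
        "amplitude": (float(np.clip(rng.normal(c.amplitude_mean, c.amplitude_sd),
                                    *c.amplitude_range))
                      if c.amplitude_range is not None
                      else max(rng.normal(c.amplitude_mean, c.amplitude_sd), 0.0)),
        "acrophase": rng.normal(c.acrophase_mean, c.acrophase_sd) % 24.0,
        "alpha": float(np.clip(rng.normal(c.alpha_mean, c.alpha_sd), -1.0, 1.0)),
        "beta": max(rng.normal(c.beta_mean, c.beta_sd), 0.1),
        "sleep_onset": float(np.clip(rng.normal(s.onset_mean, s.onset_sd),
                                     20.0, 23.9)),
        "sleep_duration": float(np.clip(
            round(rng.normal(s.duration_mean, s.duration_sd)), 240, 780)),
        "mpa_minutes": float(max(round(rng.normal(a.mpa_minutes_mean,
                                                  a.mpa_minutes_sd)), 0)),
        "vpa_minutes": float(max(round(rng.normal(a.vpa_minutes_mean,
                                                  a.vpa_minutes_sd)), 0)),
    }


def _cosinor_log_level(p: dict, clock_hours: np.ndarray) -> np.ndarray:
    r = np.cos(2.0 * np.pi * (clock_hours - p["acrophase"]) / 24.0)
    logistic = 1.0 / (1.0 + np.exp(-p["beta"] * (r - p["alpha"])))
    return p["minimum_level"] + p["amplitude"] * logistic


def _bout_clock_minutes(p: dict) -> tuple[np.ndarray, np.ndarray]:
    """Clock minutes (whole) of the planted VPA and MPA bouts: one block
    centred on the acrophase, VPA in the middle flanked by MPA."""
    total = int(p["mpa_minutes"] + p["vpa_minutes"])
    if total == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    centre = int(round(p["acrophase"] * 60.0)) % 1440
    start = centre - total // 2
    block = (start + np.arange(total)) % 1440
    v = int(p["vpa_minutes"])
    mid = total // 2
    v_lo = mid - v // 2
    vpa = block[v_lo:v_lo + v]
    mpa = np.concatenate([block[:v_lo], block[v_lo + v:]])
    return vpa.astype(int), mpa.astype(int)


def true_composition(config: SimulationConfig, participant: dict,
                     cutpoints: CutPoints = CutPoints()) -> np.ndarray:
    """Exact daily minutes implied by the planted sleep window and
    intensity schedule, for a representative (noise-free) day.

    Sleep = planted window duration; planted VPA/MPA bout minutes count
    to their bands; the remaining waking minutes are classified by the
    noise-free cosinor ENMO level against the cut-points.  Sums to 1440.
    """
    p = participant
    onset_min = int(round(p["sleep_onset"] * 60.0)) % 1440
    dur = int(p["sleep_duration"])
    sleep_mask = np.zeros(1440, dtype=bool)
    sleep_mask[(onset_min + np.arange(dur)) % 1440] = True

    vpa_idx, mpa_idx = _bout_clock_minutes(p)
    bout_mask = np.zeros(1440, dtype=bool)
    vpa = int(np.sum(~sleep_mask[vpa_idx]))
    mpa = int(np.sum(~sleep_mask[mpa_idx]))
    bout_mask[vpa_idx] = True
    bout_mask[mpa_idx] = True

    waking = ~sleep_mask & ~bout_mask
    clock = (np.arange(1440) + 0.5) / 60.0
    enmo = np.maximum(np.exp(_cosinor_log_level(p, clock)) - 1.0, 0.0)
    st = int(np.sum(waking & (enmo < cutpoints.st_upper)))
    lpa = int(np.sum(waking & (enmo >= cutpoints.st_upper)
                     & (enmo < cutpoints.mpa_lower)))
    extra_m = int(np.sum(waking & (enmo >= cutpoints.mpa_lower)
                         & (enmo < cutpoints.vpa_lower)))
    extra_v = int(np.sum(waking & (enmo >= cutpoints.vpa_lower)))
    comp = np.array([dur, st, lpa, mpa + extra_m, vpa + extra_v], dtype=float)
    assert comp.sum() == 1440
    return comp


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def _simulate_series(cfg: SimulationConfig, p: dict, pid: str,
                     rng: np.random.Generator) -> EpochSeries:
    step = cfg.epoch_seconds
    per_min = 60 // step
    n_days = cfg.n_days
    start = pd.Timestamp(cfg.start_monday) - pd.Timedelta(hours=12)
    n_epochs = (n_days + 1) * 86400 // step
    abs_hours = 12.0 + np.arange(n_epochs) * (step / 3600.0)
    clock = abs_hours % 24.0

    log_level = _cosinor_log_level(p, clock)
    if cfg.noise_sd > 0:
        log_level = log_level + rng.normal(0.0, cfg.noise_sd, n_epochs)
    enmo = np.maximum(np.exp(log_level) - 1.0, 0.0)

    z = rng.uniform(-60.0, 60.0, n_epochs)  # waking wrist movement

    # planted sleep windows, one per night (evening of day 0 .. day n_days)
    s = cfg.sleep
    onset_abs_min = []
    for night in range(n_days + 1):
        onset_h = p["sleep_onset"] + rng.normal(0.0, s.night_onset_jitter_sd)
        onset_abs_min.append(int(round(night * 1440 + onset_h * 60.0)))
    dur = int(p["sleep_duration"])

    for om in onset_abs_min:
        a = (om - 720) * per_min           # series starts at abs minute 720
        b = a + dur * per_min
        a, b = max(a, 0), min(b, n_epochs)
        if b <= a:
            continue
        resting = rng.uniform(-45.0, 45.0)
        z[a:b] = resting + rng.normal(0.0, s.resting_z_jitter_sd, b - a)
        # awakenings: high-variability, raised-ENMO whole-minute bouts
        n_awake = rng.poisson(s.n_awakenings_mean)
        placed = []
        length = int(round(s.awakening_length_min))
        sep = int(round(s.awakening_separation_min))
        margin = max(sep + 5, 10)  # minutes clear of the window edges
        attempts = 0
        while len(placed) < n_awake and attempts < 50 * max(n_awake, 1):
            attempts += 1
            if dur - margin - length <= margin:
                break
            st_min = int(rng.integers(margin, dur - margin - length))
            if any(abs(st_min - q) < length + sep for q in placed):
                continue
            placed.append(st_min)
            wa = a + st_min * per_min
            wb = wa + length * per_min
            if wb > n_epochs:
                continue
            z[wa:wb] = rng.uniform(-60.0, 60.0, wb - wa)
            enmo[wa:wb] = np.exp(rng.uniform(3.0, 4.1, wb - wa)) - 1.0

    # planted MPA/VPA bouts on each complete day, skipping sleep minutes
    act = cfg.activity
    vpa_idx, mpa_idx = _bout_clock_minutes(p)
    for day in range(1, n_days + 1):
        mult = max(1.0 + rng.normal(0.0, act.day_to_day_sd), 0.0)
        for idx, rng_mg, minutes in ((vpa_idx, act.vpa_enmo_range, p["vpa_minutes"]),
                                     (mpa_idx, act.mpa_enmo_range, p["mpa_minutes"])):
            n_keep = int(round(minutes * mult))
            for m in idx[:n_keep]:
                am = day * 1440 + m - 720
                a = am * per_min
                b = a + per_min
                if a < 0 or b > n_epochs:
                    continue
                enmo[a:b] = rng.uniform(rng_mg[0], rng_mg[1], per_min)
                z[a:b] = rng.uniform(-60.0, 60.0, per_min)

    return EpochSeries(pid, start, step, enmo, z)


# ---------------------------------------------------------------------------
# SDQ item synthesis
# ---------------------------------------------------------------------------

_SUBSCALE_SHARE = {"emotional": 0.25, "conduct": 0.23,
                   "hyperactivity": 0.27, "peer": 0.25}


def _items_from_total(total: int, rng: np.random.Generator) -> dict:
    """Distribute a total-difficulties score over the four problem
    subscales (capped at 10) and each subscale over its five 0-2 items."""
    shares = np.array(list(_SUBSCALE_SHARE.values()))
    sub = rng.multinomial(total, shares)
    # redistribute overflow beyond the 0-10 subscale range
    for _ in range(40):
        over = sub - 10
        if (over <= 0).all():
            break
        excess = int(over[over > 0].sum())
        sub = np.minimum(sub, 10)
        room = 10 - sub
        for _k in range(excess):
            open_idx = np.nonzero(room > 0)[0]
            j = open_idx[int(rng.integers(len(open_idx)))]
            sub[j] += 1
            room[j] -= 1
    items = {}
    for name, score in zip(_SUBSCALE_SHARE, sub):
        vals = np.zeros(5, dtype=int)
        for _k in range(int(score)):       # spread points over items
            open_idx = np.nonzero(vals < 2)[0]
            vals[open_idx[int(rng.integers(len(open_idx)))]] += 1
        items[name] = vals
    items["prosocial"] = rng.binomial(2, 0.7, 5)
    return items


# standard 25-item layout: item number -> (subscale, reverse-scored)
SDQ_ITEM_MAP = {
    1: ("prosocial", False), 2: ("hyperactivity", False), 3: ("emotional", False),
    4: ("prosocial", False), 5: ("conduct", False), 6: ("peer", False),
    7: ("conduct", True), 8: ("emotional", False), 9: ("prosocial", False),
    10: ("hyperactivity", False), 11: ("peer", True), 12: ("conduct", False),
    13: ("emotional", False), 14: ("peer", True), 15: ("hyperactivity", False),
    16: ("emotional", False), 17: ("prosocial", False), 18: ("conduct", False),
    19: ("peer", False), 20: ("prosocial", False), 21: ("hyperactivity", True),
    22: ("conduct", False), 23: ("peer", False), 24: ("emotional", False),
    25: ("hyperactivity", True),
}


def _item_vector(items_by_subscale: dict) -> np.ndarray:
    """Raw responses for the 25 items (reverse-scored items inverted back
    to the response scale)."""
    counters = {k: 0 for k in items_by_subscale}
    out = np.zeros(25, dtype=int)
    for item_no in range(1, 26):
        sub, rev = SDQ_ITEM_MAP[item_no]
        val = int(items_by_subscale[sub][counters[sub]])
        counters[sub] += 1
        out[item_no - 1] = 2 - val if rev else val
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    participants: pd.DataFrame
    series: list
    ground_truth: dict


def simulate_cohort(config: SimulationConfig,
                    generate_signal: bool = True) -> Cohort:
    """Generate a full synthetic cohort.

    Returns participants (covariates + SDQ items + true compositions),
    one EpochSeries per participant (unless ``generate_signal`` is False,
    for regression-level simulations that only need compositions and
    outcomes), and a ground-truth record of every planted parameter.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cov = cfg.covariates
    out = cfg.outcome
    g = clr_gradient_for_betas(out.pivot_betas)
    school_effects = rng.normal(0.0, out.school_sd, cfg.n_schools)

    rows, series, truth_rows = [], [], []
    n_clipped = 0
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:04d}"
        school = i % cfg.n_schools
        girl = rng.random() < cov.p_girl
        child = rng.random() < cov.p_child
        age = (rng.normal(cov.child_age_mean, cov.child_age_sd) if child
               else rng.normal(cov.adolescent_age_mean, cov.adolescent_age_sd))
        eimd = int(np.clip(round(rng.normal(cov.eimd_mean, cov.eimd_sd)), 1, 10))
        bmiz = rng.normal(cov.bmiz_mean, cov.bmiz_sd)

        p = _draw_participant(cfg, rng)
        comp = true_composition(cfg, p)
        comp_pos = replace_zeros(comp, delta=0.5)
        lin = (out.intercept + float(g @ np.log(comp_pos))
               + out.coef_sex_girl * girl + out.coef_adolescent * (not child)
               + out.coef_eimd * eimd + out.coef_bmiz * bmiz
               + school_effects[school])
        latent = lin + rng.normal(0.0, out.residual_sd)
        total = int(round(latent))
        if total < 0 or total > 40:
            n_clipped += 1
            total = int(np.clip(total, 0, 40))
        items = _items_from_total(total, rng)
        item_vec = _item_vector(items)

        row = {
            "participant_id": pid, "school_id": f"S{school + 1:02d}",
            "sex": "girl" if girl else "boy", "age": round(float(age), 2),
            "age_group": "child" if child else "adolescent",
            "eimd_decile": eimd, "bmiz": round(float(bmiz), 3),
        }
        row.update({f"sdq_item_{k:02d}": int(v)
                    for k, v in zip(range(1, 26), item_vec)})
        rows.append(row)

        truth_rows.append({
            "participant_id": pid, "school_id": f"S{school + 1:02d}",
            **p, **{f"true_{b}": comp[j] for j, b in enumerate(PARTS)},
            "linear_predictor": lin, "sdq_total": total,
        })

        if generate_signal:
            series.append(_simulate_series(cfg, p, pid, rng))

    participants = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    ground_truth = {
        "config": asdict(cfg),
        "clr_gradient": g.tolist(),
        "pivot_betas": pivot_beta_from_clr_gradient(g),
        "school_effects": school_effects.tolist(),
        "clipping_rate": n_clipped / cfg.n_participants,
        "participants": truth,
    }
    return Cohort(participants, series, ground_truth)
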