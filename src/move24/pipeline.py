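"""Pipeline driver: simulate -> metrics -> associate -> goldilocks.

Each stage reads and writes tidy CSV/JSON under an output directory;
every table is stamped with the configuration hash and seed so a run is
reproducible bit-for-bit from config + seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .accel import (CutPoints, average_acceleration, average_time_use,
                    classify_time_use, intensity_gradient, screen_valid_days)
from .coda import CompositionMentalHealthModel, PARTS
from .cohort import adjusted_group_means, metric_association
from .epochs import EpochSeries
from .goldilocks import goldilocks_search, radar_data
from .rhythm import ExtendedCosinorModel, nonparametric_rhythm
from .sdq import score_cohort
from .sleep import detect_all_nights, summarize_sleep
from .synthetic import SimulationConfig, simulate_cohort

log = logging.getLogger("move24")

OUTCOMES = ("total_difficulties", "internalising", "externalising")


@dataclass
class RunConfig:
    """Run-level configuration for the pipeline driver."""
    output_dir: str = "move24_out"
    epochs_dir: str | None = None          # defaults to <output_dir>/epochs
    participants_file: str | None = None
    seed: int = 0
    cutpoints: CutPoints = field(default_factory=CutPoints)
    grid_step: int = 10
    zone_fraction: float = 0.05
    truncation_k: float = 3.0
    min_weekdays: int = 3
    min_weekend: int = 1
    stratify_on_sex: bool = True
    zero_delta: float | None = None        # None -> half min positive per part
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if self.epochs_dir is None:
            self.epochs_dir = str(Path(self.output_dir) / "epochs")
        if self.participants_file is None:
            self.participants_file = str(Path(self.output_dir) / "participants.csv")
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        cut = raw.pop("cutpoints", {})
        cfg = cls(**raw)
        if cut:
            cfg.cutpoints = dataclasses.replace(cfg.cutpoints, **cut)
        for k, v in sim.items():
            setattr(cfg.simulation, k, v)
        cfg.simulation.seed = cfg.seed
        return cfg

    def stamp(self) -> str:
        cfg = dataclasses.asdict(self)
        for path_field in ("output_dir", "epochs_dir", "participants_file"):
            cfg.pop(path_field, None)   # hash the analysis config, not paths
        h = mio.config_hash(cfg)
        return f"config_hash={h} seed={self.seed}"


def stage_simulate(cfg: RunConfig) -> dict:
    """Generate the synthetic cohort and write epoch files, the
    participant table and the ground truth."""
    cohort = simulate_cohort(cfg.simulation)
    out = Path(cfg.output_dir)
    stamp = cfg.stamp()
    for s in cohort.series:
        mio.write_epochs(s, Path(cfg.epochs_dir) / f"{s.participant_id}.csv", stamp)
    mio.write_table(cohort.participants, cfg.participants_file, stamp, index=False)
    truth = dict(cohort.ground_truth)
    truth["participants"] = cohort.ground_truth["participants"].to_dict(orient="records")
    mio.write_json(truth, out / "ground_truth.json")
    log.info("simulated %d participants", len(cohort.series))
    return {"n_participants": len(cohort.series)}


def participant_metrics(series: EpochSeries, cfg: RunConfig) -> pd.Series | None:
    """All movement-behaviour characteristics for one participant, or
    None when the valid-wear criteria are unmet."""
    days, valid = screen_valid_days(series, cfg.min_weekdays, cfg.min_weekend)
    if not valid:
        return None
    windows = detect_all_nights(series)
    sleep_summary = summarize_sleep(windows)
    per_day = classify_time_use(series, cfg.cutpoints, windows, days=days)
    tu = average_time_use(per_day)
    avacc = average_acceleration(series, days=days)
    ig_slope, ig_icpt, ig_r2 = intensity_gradient(series, days=days)
    cos = ExtendedCosinorModel(series, days=days).fit()
    np_rhythm = nonparametric_rhythm(series, days=days)
    out = pd.Series({"participant_id": series.participant_id,
                     "n_valid_days": float(len(days))})
    out = pd.concat([out, tu, sleep_summary, pd.Series({
        "avg_acceleration": avacc, "intensity_gradient": ig_slope,
        "ig_intercept": ig_icpt, "ig_r_squared": ig_r2,
        "cosinor_minimum": cos.minimum_level, "cosinor_amplitude": cos.amplitude,
        "cosinor_mesor": cos.mesor, "cosinor_acrophase": cos.acrophase,
        "cosinor_alpha": cos.alpha, "cosinor_beta": cos.beta,
        "cosinor_converged": float(cos.converged), "cosinor_flat": float(cos.flat),
    }), np_rhythm.astype(float)])
    return out


def stage_metrics(cfg: RunConfig) -> pd.DataFrame:
    """Compute per-participant metric table from epoch files; excluded
    participants are listed with the failed criterion."""
    out = Path(cfg.output_dir)
    files = sorted(Path(cfg.epochs_dir).glob("*.csv"))
    if not files:
        raise RuntimeError("metrics stage: no epoch files found")
    rows, excluded = [], []
    for f in files:
        series = mio.read_epochs(f)
        m = participant_metrics(series, cfg)
        if m is None:
            excluded.append({"participant_id": series.participant_id,
                             "reason": "valid-wear criteria unmet"})
            continue
        rows.append(m)
    metrics = pd.DataFrame(rows)
    mio.write_table(metrics, out / "metrics.csv", cfg.stamp(), index=False)
    mio.write_table(pd.DataFrame(excluded,
                                 columns=["participant_id", "reason"]),
                    out / "exclusions.csv", cfg.stamp(), index=False)
    log.info("metrics: %d included, %d excluded", len(rows), len(excluded))
    return metrics


def _analysis_frame(cfg: RunConfig, metrics: pd.DataFrame | None = None) -> pd.DataFrame:
    out = Path(cfg.output_dir)
    if metrics is None:
        metrics = mio.read_table(out / "metrics.csv")
    participants = mio.read_table(cfg.participants_file)
    scored = score_cohort(participants)
    df = metrics.merge(scored, on="participant_id", how="inner")
    df["sex_girl"] = (df["sex"] == "girl").astype(float)
    df["adolescent"] = (df["age_group"] == "adolescent").astype(float)
    return df


def stage_associate(cfg: RunConfig, metrics: pd.DataFrame | None = None) -> dict:
    """Compositional models per outcome plus single-characteristic
    mixed-model associations."""
    out = Path(cfg.output_dir)
    df = _analysis_frame(cfg, metrics)
    covars = ["sex_girl", "age", "eimd_decile", "bmiz"]

    comp_rows, summary = [], {}
    for outcome in OUTCOMES:
        model = CompositionMentalHealthModel.from_dataframe(
            df, outcome, covariates=covars, zero_delta=cfg.zero_delta)
        res = model.fit(stratify_on_sex=cfg.stratify_on_sex)
        summary[outcome] = {
            "omnibus_p": res.omnibus_p, "loglik": res.loglik,
            "r_squared": res.r_squared, "vif_range": list(res.vif_range),
            "follow_up_performed": res.follow_up_performed,
        }
        for e in res.effects.values():
            comp_rows.append({"outcome": outcome, "behaviour": e.behaviour,
                              "beta": e.beta, "ci_low": e.ci_low,
                              "ci_high": e.ci_high, "p": e.p,
                              "omnibus_p": res.omnibus_p})
    comp_table = pd.DataFrame(comp_rows)
    mio.write_table(comp_table, out / "composition_models.csv", cfg.stamp(),
                    index=False)

    # adjusted sex / age-group comparisons of the main characteristics
    group_rows = []
    comparison_metrics = {"sleep": True, "st": True, "lpa": True, "mpa": True,
                          "vpa": True, "sleep_efficiency_pct": False,
                          "cosinor_acrophase": False, "avg_acceleration": True,
                          "intensity_gradient": True}
    for group in ("sex", "age_group"):
        for metric, add_bmiz in comparison_metrics.items():
            cov = ["eimd_decile"] + (["bmiz"] if add_bmiz else [])
            try:
                t = adjusted_group_means(df, metric, group, covariates=cov)
            except ValueError:
                continue
            for level, row in t.iterrows():
                group_rows.append({"metric": metric, "group": group,
                                   "level": level, **row.to_dict()})
    mio.write_table(pd.DataFrame(group_rows), out / "group_comparisons.csv",
                    cfg.stamp(), index=False)

    metric_rows = []
    characteristics = {
        "sleep_efficiency_pct": False, "sleep_onset_hours": False,
        "n_awakenings": False, "cosinor_mesor": False,
        "cosinor_amplitude": False, "cosinor_acrophase": False,
        "is": False, "iv": False, "m10": False, "l5": False,
        "avg_acceleration": True, "intensity_gradient": True,
    }
    for outcome in OUTCOMES:
        for exposure, add_bmiz in characteristics.items():
            cov = ["sex_girl", "eimd_decile", "age"] + (["bmiz"] if add_bmiz else [])
            r = metric_association(df, exposure, outcome, covariates=cov,
                                   stratify_on_sex=cfg.stratify_on_sex)
            metric_rows.append(r.to_row())
    mio.write_table(pd.DataFrame(metric_rows), out / "metric_associations.csv",
                    cfg.stamp(), index=False)
    mio.write_json({"stamp": cfg.stamp(), "composition_models": summary},
                   out / "association_summary.json")
    return summary


def stage_goldilocks(cfg: RunConfig, metrics: pd.DataFrame | None = None) -> dict:
    """Optimal time-use zone search for outcomes whose composition model
    passed the omnibus test (the search is skipped, with a notice, for
    the others)."""
    out = Path(cfg.output_dir)
    df = _analysis_frame(cfg, metrics)
    covars = ["sex_girl", "age", "eimd_decile", "bmiz"]
    comps = df[list(PARTS)].to_numpy(dtype=float)

    summary = {}
    for outcome in OUTCOMES:
        model = CompositionMentalHealthModel.from_dataframe(
            df, outcome, covariates=covars, zero_delta=cfg.zero_delta)
        mixed = model.fit(stratify_on_sex=False)
        if not mixed.follow_up_performed:
            log.info("goldilocks: %s skipped (omnibus p = %.3f)",
                     outcome, mixed.omnibus_p)
            summary[outcome] = {"skipped": True, "omnibus_p": mixed.omnibus_p}
            continue
        # aim-3 prediction model is a plain fixed-effects regression
        ols = model.fit(method="ols", stratify_on_sex=False)
        res = goldilocks_search(comps, ols, outcome=outcome,
                                k=cfg.truncation_k, step=cfg.grid_step,
                                fraction=cfg.zone_fraction)
        mio.write_table(radar_data(res.optimal_composition,
                                   res.sample_mean_composition),
                        out / f"radar_{outcome}.csv", cfg.stamp())
        zone = pd.DataFrame(res.grid[res.zone_mask], columns=PARTS)
        zone["prediction"] = res.predictions[res.zone_mask]
        mio.write_table(zone, out / f"zone_{outcome}.csv", cfg.stamp(),
                        index=False)
        summary[outcome] = {
            "skipped": False, "omnibus_p": mixed.omnibus_p,
            "grid_size": res.grid_size, "zone_size": res.zone_size,
            "optimal_composition": dict(zip(PARTS, res.optimal_composition)),
            "sample_mean_composition": dict(zip(PARTS,
                                                res.sample_mean_composition)),
        }
    mio.write_json({"stamp": cfg.stamp(), "goldilocks": summary},
                   out / "goldilocks_summary.json")
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order; any stage failure halts with its name."""
    bundle = {}
    for name, stage in (("simulate", stage_simulate),
                        ("metrics", stage_metrics),
                        ("associate", stage_associate),
                        ("goldilocks", stage_goldilocks)):
        try:
            bundle[name] = stage(cfg)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
    mio.write_json({"stamp": cfg.stamp(),
                    "stages": {k: "ok" for k in bundle}},
                   Path(cfg.output_dir) / "run_summary.json")
    return bundle
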