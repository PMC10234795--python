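"""Strengths and Difficulties Questionnaire (SDQ) scoring.

25 items on a 0-2 scale form five subscales (emotional, conduct,
hyperactivity, peer, prosocial; five items each, subscale range 0-10).
Total difficulties (0-40) sums the four problem subscales — prosocial,
the positive subscale, is excluded.  Community-sample composites:
internalising = emotional + peer; externalising = conduct +
hyperactivity.  Scores can be classified on a configurable four-band
table (close to average / slightly raised / high / very high).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import SDQ_ITEM_MAP

SUBSCALES = ("emotional", "conduct", "hyperactivity", "peer", "prosocial")
PROBLEM_SUBSCALES = ("emotional", "conduct", "hyperactivity", "peer")

# Default four-band cutoffs (lower bounds) for the self-completed SDQ.
# Not printed in every report that uses them; ship as configuration.
DEFAULT_BANDS = {
    "total_difficulties": (0, 15, 18, 20),
    "emotional": (0, 5, 6, 7),
    "conduct": (0, 4, 5, 6),
    "hyperactivity": (0, 6, 7, 8),
    "peer": (0, 3, 4, 5),
    "prosocial": None,   # prosocial bands run in the opposite direction
}
BAND_LABELS = ("close to average", "slightly raised", "high", "very high")


def band_for(score: float, cutoffs) -> str:
    for label, lo in zip(reversed(BAND_LABELS), reversed(cutoffs)):
        if score >= lo:
            return label
    return BAND_LABELS[0]


def score_sdq(items, item_map: dict = SDQ_ITEM_MAP, bands: dict = DEFAULT_BANDS,
              min_items: int = 3) -> pd.Series:
    """Score one participant's 25 item responses.

    Reverse-scored items are inverted per the item map.  A subscale with
    missing items is pro-rated (mean of present items x 5, rounded) when
    at least ``min_items`` are present, otherwise set missing; composites
    involving a missing subscale are missing.
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (25,):
        raise ValueError("expected 25 item responses")
    valid = ~np.isnan(items)
    if np.any((items[valid] < 0) | (items[valid] > 2)):
        raise ValueError("item responses must be 0, 1 or 2")

    contrib = {s: [] for s in SUBSCALES}
    for item_no in range(1, 26):
        sub, rev = item_map[item_no]
        v = items[item_no - 1]
        contrib[sub].append(2 - v if rev else v)

    scores, prorated = {}, []
    for s in SUBSCALES:
        vals = np.asarray(contrib[s], dtype=float)
        ok = ~np.isnan(vals)
        if ok.all():
            scores[s] = float(vals.sum())
        elif ok.sum() >= min_items:
            scores[s] = float(round(vals[ok].mean() * 5.0))
            prorated.append(s)
        else:
            scores[s] = np.nan

    problems = [scores[s] for s in PROBLEM_SUBSCALES]
    total = float(np.sum(problems)) if not np.any(np.isnan(problems)) else np.nan
    internal = (scores["emotional"] + scores["peer"]
                if not (np.isnan(scores["emotional"]) or np.isnan(scores["peer"]))
                else np.nan)
    external = (scores["conduct"] + scores["hyperactivity"]
                if not (np.isnan(scores["conduct"]) or np.isnan(scores["hyperactivity"]))
                else np.nan)
    out = {**scores, "total_difficulties": total,
           "internalising": internal, "externalising": external,
           "prorated_subscales": ",".join(prorated)}
    if bands and bands.get("total_difficulties") and not np.isnan(total):
        out["band"] = band_for(total, bands["total_difficulties"])
    else:
        out["band"] = None
    return pd.Series(out)


def score_cohort(participants: pd.DataFrame, item_prefix: str = "sdq_item_",
                 **kwargs) -> pd.DataFrame:
    """Score every row of a participant table holding 25 item columns."""
    cols = [f"{item_prefix}{k:02d}" for k in range(1, 26)]
    scored = participants.apply(
        lambda r: score_sdq(r[cols].to_numpy(dtype=float), **kwargs), axis=1)
    return pd.concat([participants.drop(columns=cols), scored], axis=1)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(var items)/var(sum))."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1.0) * (1.0 - item_var / total_var))
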