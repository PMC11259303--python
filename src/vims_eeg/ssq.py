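"""Simulator Sickness Questionnaire (SSQ) scoring.

Sixteen symptoms are each rated on a four-point scale (0 none, 1
slight, 2 moderate, 3 severe).  Items map onto three overlapping
subscales — Nausea (N), Oculomotor (O), Disorientation (D) — each the
sum of seven designated items (an item may count towards two
subscales), following the Kennedy et al. scoring table, which is the
only published 16-item / 3-subscale scheme using the weights below.
Subscale scores are the raw sums times their weights (N x 9.54,
O x 7.58, D x 13.92) and the total is

    SSQ_total = 3.74 * (raw_N + raw_O + raw_D)

which is algebraically identical to evaluating the weighted subscales
divided by their own weights and scaling by 3.74 (the "as-printed"
reciprocal-weight form; both entry points are provided).  The maximum
total is 3.74 * 63 = 235.62; dividing by it gives the normalized target
used by the sickness-level predictor's sigmoid output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SSQ_ITEMS", "SUBSCALE_ITEMS", "WEIGHTS", "TOTAL_FACTOR", "MAX_TOTAL",
    "SSQResponse", "SSQScore", "subscale_scores", "total_score",
    "total_score_as_printed", "normalized_total", "average_by_video",
    "read_ssq_csv", "write_ssq_csv", "score_table",
]

SSQ_ITEMS = (
    "general discomfort", "fatigue", "headache", "eyestrain",
    "difficulty focusing", "increased salivation", "sweating", "nausea",
    "difficulty concentrating", "fullness of head", "blurred vision",
    "dizzy (eyes open)", "dizzy (eyes closed)", "vertigo",
    "stomach awareness", "burping",
)

#: Kennedy item->subscale table (1-based item numbers, 7 items each).
SUBSCALE_ITEMS: dict[str, tuple[int, ...]] = {
    "nausea": (1, 6, 7, 8, 9, 15, 16),
    "oculomotor": (1, 2, 3, 4, 5, 9, 11),
    "disorientation": (5, 8, 10, 11, 12, 13, 14),
}

WEIGHTS = {"nausea": 9.54, "oculomotor": 7.58, "disorientation": 13.92}
TOTAL_FACTOR = 3.74
#: 3.74 x (3 subscales x 7 items x max score 3) = 235.62
MAX_TOTAL = TOTAL_FACTOR * sum(3 * len(v) for v in SUBSCALE_ITEMS.values())


@dataclass
class SSQResponse:
    """One questionnaire: 16 integer item scores in {0, 1, 2, 3}."""

    items: np.ndarray
    subject_id: int = -1
    video_id: int = -1

    def __post_init__(self):
        self.items = np.asarray(self.items, dtype=int)
        if self.items.shape != (16,):
            raise ValueError(f"expected 16 item scores, got shape {self.items.shape}")
        if self.items.min() < 0 or self.items.max() > 3:
            raise ValueError("item scores must lie in 0..3")


@dataclass
class SSQScore:
    """Raw and weighted subscale scores plus the total."""

    raw_nausea: int
    raw_oculomotor: int
    raw_disorientation: int

    @property
    def weighted_nausea(self) -> float:
        return self.raw_nausea * WEIGHTS["nausea"]

    @property
    def weighted_oculomotor(self) -> float:
        return self.raw_oculomotor * WEIGHTS["oculomotor"]

    @property
    def weighted_disorientation(self) -> float:
        return self.raw_disorientation * WEIGHTS["disorientation"]

    @property
    def total(self) -> float:
        return TOTAL_FACTOR * (self.raw_nausea + self.raw_oculomotor
                               + self.raw_disorientation)

    @property
    def total_norm(self) -> float:
        return self.total / MAX_TOTAL


def subscale_scores(resp: SSQResponse) -> SSQScore:
    """Raw subscale sums under the Kennedy item mapping."""
    sums = {name: int(sum(resp.items[i - 1] for i in idx))
            for name, idx in SUBSCALE_ITEMS.items()}
    return SSQScore(sums["nausea"], sums["oculomotor"], sums["disorientation"])


def total_score(resp: SSQResponse) -> float:
    """Total SSQ score, 3.74 x (sum of the three raw subscale sums)."""
    return subscale_scores(resp).total


def total_score_as_printed(resp: SSQResponse) -> float:
    """Reciprocal-weight form: 3.74 x sum of weighted subscales divided
    by their own weights.  Identical to :func:`total_score` by algebra;
    kept as a separate entry point so the identity is testable."""
    s = subscale_scores(resp)
    return TOTAL_FACTOR * (s.weighted_nausea / WEIGHTS["nausea"]
                           + s.weighted_oculomotor / WEIGHTS["oculomotor"]
                           + s.weighted_disorientation / WEIGHTS["disorientation"])


def normalized_total(resp: SSQResponse) -> float:
    return total_score(resp) / MAX_TOTAL


def score_table(responses: list[SSQResponse]) -> pd.DataFrame:
    """Per-response score table with raw/weighted subscales and totals."""
    rows = []
    for r in responses:
        s = subscale_scores(r)
        rows.append({
            "subject_id": r.subject_id, "video_id": r.video_id,
            **{f"item_{i + 1}": int(r.items[i]) for i in range(16)},
            "raw_nausea": s.raw_nausea, "raw_oculomotor": s.raw_oculomotor,
            "raw_disorientation": s.raw_disorientation,
            "weighted_nausea": s.weighted_nausea,
            "weighted_oculomotor": s.weighted_oculomotor,
            "weighted_disorientation": s.weighted_disorientation,
            "total": s.total, "total_norm": s.total_norm,
        })
    return pd.DataFrame(rows)


def average_by_video(responses: list[SSQResponse]):
    """Cross-subject summaries.

    Returns ``(per_video, per_item)``: mean total per video (averaging
    over subjects), and mean/sd per item over all responses.
    """
    if not responses:
        raise ValueError("no responses to average")
    df = score_table(responses)
    per_video = df.groupby("video_id")["total"].agg(["mean", "std", "count"])
    item_cols = [f"item_{i}" for i in range(1, 17)]
    per_item = pd.DataFrame({
        "mean": df[item_cols].mean(),
        "sd": df[item_cols].std(ddof=0),
    })
    return per_video, per_item


def write_ssq_csv(responses: list[SSQResponse], path) -> None:
    cols = ["subject_id", "video_id"] + [f"item_{i}" for i in range(1, 17)]
    score_table(responses)[cols].to_csv(path, index=False)


def read_ssq_csv(path) -> list[SSQResponse]:
    df = pd.read_csv(path)
    needed = [f"item_{i}" for i in range(1, 17)]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"SSQ table missing columns: {missing}")
    return [SSQResponse(items=row[needed].to_numpy(dtype=int),
                        subject_id=int(row.get("subject_id", -1)),
                        video_id=int(row.get("video_id", -1)))
            for _, row in df.iterrows()]
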