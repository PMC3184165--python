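"""Behavioral readouts: AIM dyskinesia scoring, cylinder-test asymmetry,
and linear dyskinesia trajectories.

Abnormal involuntary movements (AIMs) are rated 0-4 in four categories
(limb, axial, orolingual, rotational/locomotor) at every monitored
timepoint; a session's score is the sum over timepoints and categories and
the cumulative score sums all rated sessions. The cylinder test counts
left/right forelimb wall touches; animals using the contralateral (left)
forelimb less than 30% of the time meet the lesion inclusion criterion.
Dyskinesia development over treatment days is summarized by a least-squares
line y = m*day + b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AIM_CATEGORIES",
    "SESSION_DAYS",
    "AIMSession",
    "CylinderTest",
    "Trajectory",
    "session_score",
    "cumulative_score",
    "percent_left_use",
    "asymmetry_change",
    "fit_trajectory",
    "predict_day_to",
    "sessions_to_frame",
]

AIM_CATEGORIES = ("limb", "axial", "orolingual", "locomotor")

#: Rating sessions run every other day over the 15-day treatment course.
SESSION_DAYS = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass
class AIMSession:
    """One dyskinesia rating session.

    ``scores`` is an (n_timepoints, 4) integer array: one 1-minute
    observation every 20 minutes, one 0-4 score per AIM category.
    """

    animal_id: str
    index: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(AIM_CATEGORIES):
            raise ValueError("scores must be (timepoints x 4 categories)")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.round(self.scores)):
                raise ValueError("AIM scores must be integers")
            self.scores = self.scores.astype(int)
        if np.any((self.scores < 0) | (self.scores > 4)):
            bad = self.scores[(self.scores < 0) | (self.scores > 4)][0]
            raise ValueError(f"AIM score {bad} outside the 0-4 scale")


@dataclass(frozen=True)
class CylinderTest:
    """Forelimb wall-touch counts for one cylinder-test occasion."""

    animal_id: str
    occasion: str  # "pre" | "post"
    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0:
            raise ValueError("touch counts must be non-negative")
        if int(self.left) != self.left or int(self.right) != self.right:
            raise ValueError("touch counts must be integers")


@dataclass(frozen=True)
class Trajectory:
    """Least-squares dyskinesia trajectory y = slope*day + intercept."""

    slope: float
    intercept: float
    residual_sd: float


def session_score(session: AIMSession, categories=AIM_CATEGORIES) -> int:
    """Sum of scores over all timepoints and the selected categories.

    ``categories`` defaults to all four AIM categories (the cumulative sum
    of all dyskinesia scores); pass a subset to drop e.g. the
    rotational/locomotor category, a common variant in this literature.
    """
    idx = [AIM_CATEGORIES.index(c) for c in categories]
    return int(session.scores[:, idx].sum())


def cumulative_score(sessions: list[AIMSession], categories=AIM_CATEGORIES) -> int:
    """Sum of session scores over all rated sessions for one animal."""
    if not sessions:
        raise ValueError("at least one session required")
    indices = [s.index for s in sessions]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate session index")
    return int(sum(session_score(s, categories) for s in sessions))


def percent_left_use(test: CylinderTest) -> tuple[float, bool]:
    """Percent left-forelimb use and the <30% inclusion flag.

    The boundary is exclusive: exactly 30% left use is excluded.
    """
    total = test.left + test.right
    if total == 0:
        raise ValueError("zero total touches")
    pct = 100.0 * test.left / total
    return pct, pct < 30.0


def asymmetry_change(pre: CylinderTest, post: CylinderTest) -> float:
    """Percentage-point change in left-forelimb use (post - pre).

    Positive values indicate improved (less asymmetric) forelimb use.
    """
    return percent_left_use(post)[0] - percent_left_use(pre)[0]


def fit_trajectory(days, scores) -> Trajectory:
    """Least-squares line through (day, session score) pairs."""
    x = np.asarray(days, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 (day, score) pairs")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct days")
    reg = sps.linregress(x, y)
    resid = y - (reg.slope * x + reg.intercept)
    sd = float(np.sqrt(resid @ resid / max(x.size - 2, 1)))
    return Trajectory(slope=float(reg.slope), intercept=float(reg.intercept), residual_sd=sd)


def predict_day_to(trajectory: Trajectory, threshold: float) -> float:
    """Day at which the fitted line reaches a threshold score.

    Solves threshold = slope*day + intercept; requires a positive slope
    when the threshold lies above the intercept.
    """
    if trajectory.slope <= 0 and threshold > trajectory.intercept:
        raise ValueError("threshold unreachable: non-positive slope")
    return (threshold - trajectory.intercept) / trajectory.slope


def sessions_to_frame(sessions: list[AIMSession]) -> pd.DataFrame:
    """Long-format export: animal, session, timepoint, category, score."""
    rows = []
    for s in sessions:
        for t in range(s.scores.shape[0]):
            for c, cat in enumerate(AIM_CATEGORIES):
                rows.append(
                    {
                        "animal_id": s.animal_id,
                        "session": s.index,
                        "timepoint": t + 1,
                        "category": cat,
                        "score": int(s.scores[t, c]),
                    }
                )
    return pd.DataFrame(rows)
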