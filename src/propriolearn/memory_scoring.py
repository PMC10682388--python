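"""Signal-detection scoring of the proprioceptive recognition-memory task.

Each 60-trial session presents three elbow angles to memorize; on half the
trials the test angle is one of them ("present"), on the other half it is a
new angle ("absent").  Responses are classified into hits, misses, false
alarms and correct rejections, from which

* sensitivity = hit / (hit + miss)
* precision   = hit / (hit + false alarm)
* d'          = Z(hit rate) - Z(false-alarm rate)

are computed.  Sensitivity is additionally broken down by the serial
position of the matched angle (1 = oldest, 3 = most recent); the
memory-preference index is position-3 sensitivity minus position-1
sensitivity, so negative values indicate better memory for older items.

A "hit" requires only a correct "present" response; naming the correct
position is tracked separately (``naming_accuracy``) and does not gate the
hit classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import norm

__all__ = [
    "MemoryTrial",
    "MemoryScore",
    "d_prime",
    "score_memory_session",
    "score_memory_table",
]


@dataclass(frozen=True)
class MemoryTrial:
    """One recognition trial: three memorized angles and a test angle.

    ``matched_position`` is None iff the trial is an absent trial;
    ``named_position`` is None iff the response was "absent".
    """

    angle1: float
    angle2: float
    angle3: float
    test_angle: float
    condition: str  # "present" | "absent"
    matched_position: Optional[int]
    response: str  # "present" | "absent"
    named_position: Optional[int]

    def __post_init__(self) -> None:
        if self.condition not in ("present", "absent"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.response not in ("present", "absent"):
            raise ValueError(f"unknown response {self.response!r}")
        if (self.matched_position is None) != (self.condition == "absent"):
            raise ValueError("matched_position must be set iff condition is present")
        if (self.named_position is None) != (self.response == "absent"):
            raise ValueError("named_position must be set iff response is present")

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.angle1, self.angle2, self.angle3)


@dataclass
class MemoryScore:
    """Signal-detection summary of one recognition-memory session."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    sensitivity: float
    precision: Optional[float]  # None when hits + false_alarms == 0
    d_prime: float
    position_sensitivity: tuple[Optional[float], Optional[float], Optional[float]]
    preference_index: Optional[float]
    naming_accuracy: Optional[float]  # correct position namings / hits

    @property
    def hit_rate(self) -> float:
        return self.hits / (self.hits + self.misses)

    @property
    def false_alarm_rate(self) -> float:
        return self.false_alarms / (self.false_alarms + self.correct_rejections)


def d_prime(
    hit_rate: float, fa_rate: float, n_present: int, n_absent: int
) -> float:
    """d' = Z(hit rate) - Z(false-alarm rate), with extreme-rate correction.

    Rates of exactly 0 or 1 are replaced by ``1/(2n)`` and ``1 - 1/(2n)``
    (n = trial count on that side) before the standard-normal quantile
    transform, so the statistic stays finite on perfect sessions.
    """
    if n_present < 1 or n_absent < 1:
        raise ValueError("trial counts must be at least 1")
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")

    def _clip(rate: float, n: int) -> float:
        if rate <= 0.0:
            return 1.0 / (2 * n)
        if rate >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate

    return float(norm.ppf(_clip(hit_rate, n_present)) - norm.ppf(_clip(fa_rate, n_absent)))


def _as_trials(trials: Iterable[MemoryTrial] | pd.DataFrame) -> list[MemoryTrial]:
    if isinstance(trials, pd.DataFrame):
        out = []
        for row in trials.itertuples(index=False):
            matched = getattr(row, "matched_position", None)
            named = getattr(row, "named_position", None)
            out.append(
                MemoryTrial(
                    angle1=float(row.angle1),
                    angle2=float(row.angle2),
                    angle3=float(row.angle3),
                    test_angle=float(row.test_angle),
                    condition=str(row.condition),
                    matched_position=None if pd.isna(matched) else int(matched),
                    response=str(row.response),
                    named_position=None if pd.isna(named) else int(named),
                )
            )
        return out
    return list(trials)


def score_memory_session(
    trials: Iterable[MemoryTrial] | pd.DataFrame,
) -> MemoryScore:
    """Score one recognition session.

    Raises
    ------
    ValueError
        If the session has no present trials or no absent trials (the
        signal-detection rates are undefined).
    """
    trial_list = _as_trials(trials)
    hits = misses = fas = crs = 0
    pos_hits = {1: 0, 2: 0, 3: 0}
    pos_n = {1: 0, 2: 0, 3: 0}
    named_correct = 0
    for t in trial_list:
        if t.condition == "present":
            pos_n[t.matched_position] += 1
            if t.response == "present":
                hits += 1
                pos_hits[t.matched_position] += 1
                if t.named_position == t.matched_position:
                    named_correct += 1
            else:
                misses += 1
        else:
            if t.response == "present":
                fas += 1
            else:
                crs += 1

    n_present = hits + misses
    n_absent = fas + crs
    if n_present == 0 or n_absent == 0:
        raise ValueError(
            "session must contain at least one present and one absent trial"
        )

    sensitivity = hits / n_present
    precision = hits / (hits + fas) if hits + fas > 0 else None
    dp = d_prime(sensitivity, fas / n_absent, n_present, n_absent)
    pos_sens = tuple(
        pos_hits[i] / pos_n[i] if pos_n[i] > 0 else None for i in (1, 2, 3)
    )
    preference = (
        pos_sens[2] - pos_sens[0]
        if pos_sens[0] is not None and pos_sens[2] is not None
        else None
    )
    naming = named_correct / hits if hits > 0 else None
    return MemoryScore(
        hits=hits,
        misses=misses,
        false_alarms=fas,
        correct_rejections=crs,
        sensitivity=sensitivity,
        precision=precision,
        d_prime=dp,
        position_sensitivity=pos_sens,
        preference_index=preference,
        naming_accuracy=naming,
    )


def score_memory_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every participant in a ``memory_trials`` table.

    Expects the long-format table written by the cohort simulator (one row
    per trial, ``participant_id`` column); returns one row per participant.
    """
    rows = []
    for pid, group in trials.groupby("participant_id", sort=True):
        s = score_memory_session(group)
        rows.append(
            {
                "participant_id": pid,
                "hits": s.hits,
                "misses": s.misses,
                "false_alarms": s.false_alarms,
                "correct_rejections": s.correct_rejections,
                "sensitivity": s.sensitivity,
                "precision": s.precision,
                "d_prime": s.d_prime,
                "pos1_sensitivity": s.position_sensitivity[0],
                "pos2_sensitivity": s.position_sensitivity[1],
                "pos3_sensitivity": s.position_sensitivity[2],
                "preference_index": s.preference_index,
                "naming_accuracy": s.naming_accuracy,
            }
        )
    return pd.DataFrame(rows)
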