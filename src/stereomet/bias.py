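"""Cognitive-bias (judgement-bias) scores from radial-maze arm-visit logs.

In the exploration-based judgement-bias task a mouse is trained in an
eight-arm radial maze in which two adjacent *positive* arms predict reward
and the two opposite *negative* arms predict mild punishment; the four
intermediate arms stay closed during training. At test all eight arms open
and the previously inaccessible arms become *ambiguous* probes: the two
adjacent to positive arms are *near-positive*, the two adjacent to negative
arms *near-negative*. Relative time spent in near-positive versus
near-negative arms reads out whether the animal interprets ambiguity
optimistically or pessimistically.

Three normalised contrast scores, each in ``[-1, 1]``:

- ``positive_arm_score  = (T_pos - T_neg) / (T_pos + T_neg)`` —
  discrimination between the trained reference arms;
- ``reference_arm_score = (T_ref - T_amb) / (T_ref + T_amb)`` —
  preference for familiar reference arms over ambiguous ones;
- ``ambiguous_arm_score = (T_npos - T_nneg) / (T_npos + T_nneg)`` —
  the judgement-bias contrast proper.

Denominators use arm time only; time in the central arena is reported
separately. A zero denominator yields ``nan`` (the score is undefined, which
is a different statement from indifference at 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ROLES",
    "ArmVisit",
    "ArmVisitLog",
    "ArmRoleMap",
    "BiasScores",
    "time_in_roles",
    "positive_arm_score",
    "reference_arm_score",
    "ambiguous_arm_score",
    "entry_summary",
    "bias_scores",
]

ROLES = ("positive", "negative", "near_positive", "near_negative", "closed")
OPEN_ROLES = ROLES[:4]
REFERENCE_ROLES = ("positive", "negative")
AMBIGUOUS_ROLES = ("near_positive", "near_negative")


@dataclass(frozen=True)
class ArmVisit:
    arm_id: int
    entry_s: float
    exit_s: float

    def __post_init__(self) -> None:
        if not self.entry_s < self.exit_s:
            raise ValueError(
                f"arm {self.arm_id}: entry_s ({self.entry_s}) must precede "
                f"exit_s ({self.exit_s})"
            )
        if self.entry_s < 0:
            raise ValueError(f"arm {self.arm_id}: negative entry_s {self.entry_s}")

    @property
    def duration_s(self) -> float:
        return self.exit_s - self.entry_s


@dataclass
class ArmVisitLog:
    """Timed arm entries/exits of one subject in one maze session."""

    subject_id: str
    session_id: str
    duration_s: float = 600.0
    visits: list[ArmVisit] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_exit = 0.0
        for v in sorted(self.visits, key=lambda v: v.entry_s):
            if v.entry_s < prev_exit:
                raise ValueError(
                    f"subject {self.subject_id} session {self.session_id}: "
                    f"overlapping visits around t={v.entry_s}s"
                )
            if v.exit_s > self.duration_s:
                raise ValueError(
                    f"subject {self.subject_id} session {self.session_id}: visit "
                    f"exits at {v.exit_s}s after session end ({self.duration_s}s)"
                )
            prev_exit = v.exit_s


class ArmRoleMap(Mapping[int, str]):
    """Assignment of the eight maze arms to roles.

    A testing map has exactly two arms per open role; a training map has two
    positive, two negative and four closed arms.
    """

    def __init__(self, roles: Mapping[int, str]):
        self._roles = {int(a): r for a, r in roles.items()}
        for arm, role in self._roles.items():
            if role not in ROLES:
                raise ValueError(f"arm {arm}: unknown role {role!r}")

    def __getitem__(self, arm: int) -> str:
        return self._roles[arm]

    def __iter__(self):
        return iter(self._roles)

    def __len__(self) -> int:
        return len(self._roles)

    def arms_with_role(self, role: str) -> tuple[int, ...]:
        return tuple(a for a, r in sorted(self._roles.items()) if r == role)

    def validate_layout(self, phase: str = "testing") -> None:
        counts = {r: len(self.arms_with_role(r)) for r in ROLES}
        if phase == "testing":
            want = {"positive": 2, "negative": 2, "near_positive": 2, "near_negative": 2}
        elif phase == "training":
            want = {"positive": 2, "negative": 2, "closed": 4}
        else:
            raise ValueError(f"phase must be 'testing' or 'training', got {phase!r}")
        for role, n in want.items():
            if counts[role] != n:
                raise ValueError(
                    f"{phase} layout needs {n} {role} arms, found {counts[role]}"
                )


#: Standard testing layout: arms 1..8 clockwise, reference pairs opposite.
DEFAULT_TEST_ROLES = ArmRoleMap(
    {1: "positive", 2: "positive", 3: "near_positive", 8: "near_positive",
     4: "near_negative", 7: "near_negative", 5: "negative", 6: "negative"}
)

#: Training layout: ambiguous arms closed.
DEFAULT_TRAIN_ROLES = ArmRoleMap(
    {1: "positive", 2: "positive", 3: "closed", 8: "closed",
     4: "closed", 7: "closed", 5: "negative", 6: "negative"}
)


@dataclass
class BiasScores:
    """All occupancy summaries and bias scores of one session."""

    positive_arm_score: float
    reference_arm_score: float
    ambiguous_arm_score: float
    rel_time: dict[str, float]
    rel_entries: dict[str, float]
    total_entries: int
    time_s: dict[str, float]
    centre_time_s: float


def time_in_roles(log: ArmVisitLog, roles: ArmRoleMap) -> dict[str, float]:
    """Seconds spent per role, plus ``'centre'`` = unaccounted session time."""
    out = {r: 0.0 for r in OPEN_ROLES}
    for v in log.visits:
        if v.arm_id not in roles:
            raise ValueError(f"visit to arm {v.arm_id} absent from the role map")
        role = roles[v.arm_id]
        if role == "closed":
            raise ValueError(f"visit to closed arm {v.arm_id}")
        out[role] += v.duration_s
    out["centre"] = max(log.duration_s - sum(out.values()), 0.0)
    return out


def _ratio_score(a: float, b: float) -> float:
    denom = a + b
    if denom <= 0:
        return math.nan
    return (a - b) / denom


def positive_arm_score(log: ArmVisitLog, roles: ArmRoleMap) -> float:
    """(time in positive - negative arms) / time in all reference arms."""
    t = time_in_roles(log, roles)
    return _ratio_score(t["positive"], t["negative"])


def reference_arm_score(log: ArmVisitLog, roles: ArmRoleMap) -> float:
    """(time in reference - ambiguous arms) / time in all arms."""
    t = time_in_roles(log, roles)
    t_ref = sum(t[r] for r in REFERENCE_ROLES)
    t_amb = sum(t[r] for r in AMBIGUOUS_ROLES)
    return _ratio_score(t_ref, t_amb)


def ambiguous_arm_score(log: ArmVisitLog, roles: ArmRoleMap) -> float:
    """(time in near-positive - near-negative arms) / time in ambiguous arms."""
    t = time_in_roles(log, roles)
    return _ratio_score(t["near_positive"], t["near_negative"])


def entry_summary(
    log: ArmVisitLog, roles: ArmRoleMap
) -> tuple[dict[str, float], int]:
    """Relative entry counts per role and the absolute total.

    Total arm entries is the task's activity measure. With zero entries the
    relative counts are undefined (``nan``).
    """
    counts = {r: 0 for r in OPEN_ROLES}
    for v in log.visits:
        role = roles[v.arm_id]
        if role == "closed":
            raise ValueError(f"visit to closed arm {v.arm_id}")
        counts[role] += 1
    total = sum(counts.values())
    if total == 0:
        rel = {r: math.nan for r in OPEN_ROLES}
    else:
        rel = {r: c / total for r, c in counts.items()}
    return rel, total


def bias_scores(log: ArmVisitLog, roles: ArmRoleMap) -> BiasScores:
    """Compute every occupancy summary and score for one session."""
    t = time_in_roles(log, roles)
    centre = t.pop("centre")
    rel_entries, total_entries = entry_summary(log, roles)
    t_ref = sum(t[r] for r in REFERENCE_ROLES)
    t_amb = sum(t[r] for r in AMBIGUOUS_ROLES)
    return BiasScores(
        positive_arm_score=_ratio_score(t["positive"], t["negative"]),
        reference_arm_score=_ratio_score(t_ref, t_amb),
        ambiguous_arm_score=_ratio_score(t["near_positive"], t["near_negative"]),
        rel_time={r: v / log.duration_s for r, v in t.items()},
        rel_entries=rel_entries,
        total_entries=total_entries,
        time_s=dict(t),
        centre_time_s=centre,
    )
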