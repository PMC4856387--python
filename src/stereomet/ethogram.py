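"""One-zero scoring of home-cage behaviour and stereotypic-bout detection.

Home-cage observation uses *one-zero sampling*: time is divided into 15-s
intervals and each behaviour category scores 1 for an interval if it occurs
at any point within it. The standard scheme observes the first 15 min of
four hours of the dark phase on two days — 8 blocks of 900 s — giving 480
intervals per subject.

A behaviour event qualifies as a *stereotypic bout* when the same movement
sequence is repeated continuously for at least 3 s (bar-mouthing, which is a
continuous behaviour) or at least three times in a row with pauses no longer
than 3 s between repetitions (cage-top twirling, back-flipping,
route-tracing, circling — discrete-repetition behaviours). Only qualifying
bouts flag intervals for a stereotypy form.

An interval is *inactive* when the animal is motionless throughout it,
brief twitches excepted; here any non-inactive event lasting more than 5 s,
or any qualifying stereotypic bout, marks the interval active. The level of
each form of stereotypy is the proportion of *active* intervals flagged for
that form (so an animal asleep most of the day can still have a high
stereotypy level while awake). Levels of different forms are not additive:
an interval flagged for two forms counts once in the combined level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STEREOTYPY_FORMS",
    "BEHAVIOURS",
    "BehaviourEvent",
    "Bout",
    "ObservationScheme",
    "SampleMatrix",
    "classify_stereotypic",
    "one_zero_sample",
    "stereotypy_level",
]

STEREOTYPY_FORMS = (
    "bar_mouthing",
    "circling",
    "cage_top_twirling",
    "back_flipping",
    "route_tracing",
)
#: Continuous-form criterion applies to bar-mouthing; the rest are discrete.
CONTINUOUS_FORMS = ("bar_mouthing",)
BEHAVIOURS = ("inactive", "active") + STEREOTYPY_FORMS


@dataclass(frozen=True)
class BehaviourEvent:
    """A timed behaviour observation.

    ``repeat_index`` carries the number of discrete repetitions (flips,
    twirls, laps) the event comprises; ``None`` means one.
    """

    behaviour: str
    start_s: float
    end_s: float
    repeat_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(
                f"unknown behaviour {self.behaviour!r}; expected one of {BEHAVIOURS}"
            )
        if not self.start_s < self.end_s:
            raise ValueError(
                f"{self.behaviour}: start_s ({self.start_s}) must precede "
                f"end_s ({self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_repeats(self) -> int:
        return 1 if self.repeat_index is None else int(self.repeat_index)


@dataclass(frozen=True)
class Bout:
    """A qualifying stereotypic episode."""

    behaviour: str
    start_s: float
    end_s: float
    n_repeats: int


@dataclass
class ObservationScheme:
    """One-zero sampling design.

    Defaults reproduce the standard home-cage design: 15-s intervals over
    the first 15 min (900 s) of the 2nd-5th hour of the dark phase on two
    days, i.e. ``2 * 4 * 900 / 15 = 480`` intervals. ``block_starts_s`` are
    seconds from each day's dark-phase onset; day ``d`` is offset by
    ``d * day_length_s``.
    """

    interval_s: float = 15.0
    block_length_s: float = 900.0
    block_starts_s: tuple[float, ...] = (3600.0, 7200.0, 10800.0, 14400.0)
    days: int = 2
    day_length_s: float = 86400.0

    def __post_init__(self) -> None:
        if self.interval_s <= 0 or self.block_length_s <= 0 or self.days < 1:
            raise ValueError("interval_s, block_length_s and days must be positive")
        n, rem = divmod(self.block_length_s, self.interval_s)
        if rem:
            raise ValueError("interval_s must divide block_length_s")
        starts = sorted(self.block_starts_s)
        for a, b in zip(starts, starts[1:]):
            if a + self.block_length_s > b:
                raise ValueError("observation blocks overlap")
        if starts and starts[-1] + self.block_length_s > self.day_length_s:
            raise ValueError("last block exceeds day length")

    @property
    def intervals_per_block(self) -> int:
        return int(self.block_length_s // self.interval_s)

    @property
    def n_intervals(self) -> int:
        return self.days * len(self.block_starts_s) * self.intervals_per_block

    def interval_starts(self) -> np.ndarray:
        """Absolute start time of every sampling interval, in order."""
        starts = []
        for day in range(self.days):
            for block in sorted(self.block_starts_s):
                t0 = day * self.day_length_s + block
                starts.extend(
                    t0 + i * self.interval_s for i in range(self.intervals_per_block)
                )
        return np.asarray(starts)


@dataclass
class SampleMatrix:
    """Per-interval one-zero indicators for one subject.

    ``data`` has one row per interval (columns: ``interval_start_s``, one
    column per stereotypy form, ``active``, ``inactive``).
    """

    subject_id: str
    data: pd.DataFrame
    n_intervals: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_intervals = len(self.data)


def _runs(events: Sequence[BehaviourEvent], max_gap_s: float) -> list[list[BehaviourEvent]]:
    runs: list[list[BehaviourEvent]] = []
    for ev in events:
        if runs and ev.start_s - runs[-1][-1].end_s <= max_gap_s:
            runs[-1].append(ev)
        else:
            runs.append([ev])
    return runs


def classify_stereotypic(
    events: Iterable[BehaviourEvent],
    min_duration_s: float = 3.0,
    min_repeats: int = 3,
    max_gap_s: float = 3.0,
) -> list[Bout]:
    """Extract qualifying stereotypic bouts from an event stream.

    Bar-mouthing (continuous form): an event qualifies iff it lasts at least
    ``min_duration_s``; overlapping or touching qualifying spans merge.
    Discrete-repetition forms: consecutive events of the same behaviour with
    inter-event pauses of at most ``max_gap_s`` (a pause of exactly 3 s keeps
    the run; strictly longer breaks it) form a run, which qualifies iff its
    repetitions total at least ``min_repeats``. Each event contributes
    ``repeat_index`` repetitions (default 1), so a single event recorded
    with three laps already qualifies. Non-stereotypic labels are ignored.
    """
    by_form: dict[str, list[BehaviourEvent]] = {f: [] for f in STEREOTYPY_FORMS}
    for ev in events:
        if ev.behaviour in by_form:
            by_form[ev.behaviour].append(ev)

    bouts: list[Bout] = []
    for form, evs in by_form.items():
        evs.sort(key=lambda e: (e.start_s, e.end_s))
        if form in CONTINUOUS_FORMS:
            qualifying = [e for e in evs if e.duration_s >= min_duration_s]
            # merge touching/overlapping qualifying spans
            for run in _runs(qualifying, max_gap_s=0.0):
                bouts.append(
                    Bout(
                        behaviour=form,
                        start_s=run[0].start_s,
                        end_s=max(e.end_s for e in run),
                        n_repeats=sum(e.n_repeats for e in run),
                    )
                )
        else:
            for run in _runs(evs, max_gap_s=max_gap_s):
                reps = sum(e.n_repeats for e in run)
                if reps >= min_repeats:
                    bouts.append(
                        Bout(
                            behaviour=form,
                            start_s=run[0].start_s,
                            end_s=max(e.end_s for e in run),
                            n_repeats=reps,
                        )
                    )
    bouts.sort(key=lambda b: (b.start_s, b.behaviour))
    return bouts


def _overlaps(start: float, end: float, t0: float, t1: float) -> bool:
    # half-open interval [t0, t1): a touch exactly at t1 belongs to the next one
    return start < t1 and end > t0


def one_zero_sample(
    events: Sequence[BehaviourEvent],
    scheme: ObservationScheme,
    subject_id: str = "",
    bouts: Optional[Sequence[Bout]] = None,
    twitch_max_s: float = 5.0,
) -> SampleMatrix:
    """Score every sampling interval with one-zero indicators.

    A stereotypy form scores 1 for an interval iff a qualifying bout of that
    form overlaps the half-open interval ``[t, t + interval)``. An interval
    is *active* iff it is flagged for any form or overlapped by a
    non-inactive event longer than ``twitch_max_s`` (shorter movements count
    as the twitches that do not break inactivity); otherwise it is
    *inactive*. Events outside all observation blocks are ignored. ``bouts``
    defaults to :func:`classify_stereotypic` of ``events``.
    """
    if bouts is None:
        bouts = classify_stereotypic(events)
    starts = scheme.interval_starts()
    width = scheme.interval_s
    n = len(starts)

    cols: dict[str, np.ndarray] = {
        form: np.zeros(n, dtype=np.int8) for form in STEREOTYPY_FORMS
    }
    active = np.zeros(n, dtype=np.int8)

    def _flag(arr: np.ndarray, a: float, b: float) -> None:
        # indices of intervals [t, t+width) overlapping (a, b)
        lo = np.searchsorted(starts, a - width, side="right")
        hi = np.searchsorted(starts, b, side="left")
        for i in range(lo, hi):
            if _overlaps(a, b, starts[i], starts[i] + width):
                arr[i] = 1

    for b in bouts:
        _flag(cols[b.behaviour], b.start_s, b.end_s)
        _flag(active, b.start_s, b.end_s)
    for ev in events:
        if ev.behaviour != "inactive" and ev.duration_s > twitch_max_s:
            _flag(active, ev.start_s, ev.end_s)

    data = pd.DataFrame({"interval_start_s": starts})
    for form in STEREOTYPY_FORMS:
        data[form] = cols[form]
    data["active"] = active
    data["inactive"] = 1 - active
    return SampleMatrix(subject_id=subject_id, data=data)


def stereotypy_level(matrix: SampleMatrix, form: str = "all") -> float:
    """Proportion of active intervals flagged for ``form``.

    ``form='all'`` uses the union over every stereotypy form (non-additive:
    an interval flagged for two forms counts once). Returns ``nan`` when no
    interval is active (the level is undefined without active time).
    """
    if form != "all" and form not in STEREOTYPY_FORMS:
        raise ValueError(f"unknown form {form!r}")
    active = matrix.data["active"].to_numpy()
    n_active = int(active.sum())
    if n_active == 0:
        return math.nan
    if form == "all":
        flagged = matrix.data[list(STEREOTYPY_FORMS)].to_numpy().max(axis=1)
    else:
        flagged = matrix.data[form].to_numpy()
    return float((flagged & active).sum() / n_active)
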