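"""Synthetic choice agents, maze sessions and ethogram streams.

Every analysis stage in this package gets a generator with *known*
parameters, so parameter recovery can be tested end to end: choice agents
with tunable sequential dependence feed the guessing-task controller, a
renewal-process maze simulator produces arm-visit logs with target role
occupancies, and a bout generator produces home-cage event streams with an
analytically known expected flagging rate.

Defaults emulate the study conditions: 80-trial guessing sessions, 600-s
(10-min) maze sessions with roughly 30% centre time and entry totals in the
50-75 range, and the 2-day x 4-block x 15-min observation scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bias import ArmRoleMap, ArmVisit, ArmVisitLog, DEFAULT_TEST_ROLES, OPEN_ROLES
from .ethogram import (
    BehaviourEvent,
    CONTINUOUS_FORMS,
    ObservationScheme,
    STEREOTYPY_FORMS,
)

__all__ = [
    "AgentSpec",
    "MazeProfile",
    "EthoProfile",
    "make_agent",
    "simulate_visit_log",
    "simulate_ethogram",
    "expected_flag_probability",
]

AGENT_KINDS = ("iid_biased", "markov_repeat", "alternator", "win_stay_lose_shift")


@dataclass
class AgentSpec:
    """A choice policy with known parameters.

    kinds
        ``iid_biased``: choose R with ``p_right`` independently each trial.
        ``markov_repeat``: repeat the previous choice with ``p_repeat``
        (first trial a fair coin) — an order-1 Markov agent whose
        sequential dependence grows with ``|p_repeat - 0.5|``.
        ``alternator``: deterministic strict alternation starting ``first``.
        ``win_stay_lose_shift``: after a rewarded trial repeat with
        ``p_stay``, after an unrewarded one switch with ``p_stay``.
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}; one of {AGENT_KINDS}")
        for key, val in self.params.items():
            if key.startswith("p_") and not 0.0 <= float(val) <= 1.0:
                raise ValueError(f"{key}={val} outside [0, 1]")


def make_agent(spec: AgentSpec):
    """Build the choice-policy callable ``agent(choices, rewards) -> side``."""
    rng = np.random.default_rng(spec.seed)
    p = spec.params

    if spec.kind == "iid_biased":
        p_right = float(p.get("p_right", 0.5))

        def agent(choices: Sequence[str], rewards: Sequence[bool]) -> str:
            return "R" if rng.random() < p_right else "L"

    elif spec.kind == "markov_repeat":
        p_repeat = float(p.get("p_repeat", 0.5))

        def agent(choices: Sequence[str], rewards: Sequence[bool]) -> str:
            if not choices:
                return "R" if rng.random() < 0.5 else "L"
            prev = choices[-1]
            if rng.random() < p_repeat:
                return prev
            return "L" if prev == "R" else "R"

    elif spec.kind == "alternator":
        first = str(p.get("first", "L"))

        def agent(choices: Sequence[str], rewards: Sequence[bool]) -> str:
            if not choices:
                return first
            return "L" if choices[-1] == "R" else "R"

    else:  # win_stay_lose_shift
        p_stay = float(p.get("p_stay", 1.0))

        def agent(choices: Sequence[str], rewards: Sequence[bool]) -> str:
            if not choices:
                return "R" if rng.random() < 0.5 else "L"
            prev = choices[-1]
            other = "L" if prev == "R" else "R"
            if rewards[-1]:
                return prev if rng.random() < p_stay else other
            return other if rng.random() < p_stay else prev

    return agent


@dataclass
class MazeProfile:
    """Target occupancy structure of a simulated 10-min maze session.

    ``occupancy`` maps each open role to its target fraction of session
    time; the remainder is centre time. Defaults give a positive-biased
    animal spending ~30% of the session in the central arena with ~60 arm
    entries. Visit durations are exponential with a common mean across
    roles, and the role of each visit is drawn proportionally to its target
    occupancy, so expected occupancies match the profile and ratio scores
    are recovered without bias.
    """

    occupancy: dict[str, float] = field(
        default_factory=lambda: {
            "positive": 0.25,
            "negative": 0.10,
            "near_positive": 0.20,
            "near_negative": 0.15,
        }
    )
    n_entries: float = 60.0
    duration_s: float = 600.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        bad = set(self.occupancy) - set(OPEN_ROLES)
        if bad:
            raise ValueError(f"unknown roles in occupancy: {sorted(bad)}")
        if any(f < 0 for f in self.occupancy.values()):
            raise ValueError("occupancy fractions must be >= 0")
        if sum(self.occupancy.values()) > 1.0 + 1e-9:
            raise ValueError("occupancy fractions sum beyond 1")
        if self.n_entries < 0:
            raise ValueError("n_entries must be >= 0")


def simulate_visit_log(
    profile: MazeProfile,
    roles: ArmRoleMap = DEFAULT_TEST_ROLES,
    subject_id: str = "sim",
    session_id: str = "test",
) -> ArmVisitLog:
    """Draw one session's arm-visit log matching the profile in expectation.

    Alternates exponential centre stays and arm visits until the session
    clock runs out (the final segment is truncated at the session end).
    A zero entry rate yields an empty log.
    """
    rng = np.random.default_rng(profile.seed)
    frac = {r: profile.occupancy.get(r, 0.0) for r in OPEN_ROLES}
    arm_total = sum(frac.values())
    if profile.n_entries <= 0 or arm_total <= 0:
        return ArmVisitLog(
            subject_id=subject_id, session_id=session_id,
            duration_s=profile.duration_s, visits=[],
        )

    mean_visit = arm_total * profile.duration_s / profile.n_entries
    mean_centre = (1.0 - arm_total) * profile.duration_s / profile.n_entries
    role_names = [r for r in OPEN_ROLES if frac[r] > 0]
    role_p = np.array([frac[r] for r in role_names])
    role_p = role_p / role_p.sum()

    visits: list[ArmVisit] = []
    t = 0.0
    while True:
        t += rng.exponential(mean_centre) if mean_centre > 0 else 0.0
        if t >= profile.duration_s:
            break
        role = role_names[rng.choice(len(role_names), p=role_p)]
        arm = int(rng.choice(roles.arms_with_role(role)))
        dur = rng.exponential(mean_visit)
        exit_s = min(t + dur, profile.duration_s)
        if exit_s > t:
            visits.append(ArmVisit(arm_id=arm, entry_s=t, exit_s=exit_s))
        t = exit_s
        if t >= profile.duration_s:
            break
    return ArmVisitLog(
        subject_id=subject_id, session_id=session_id,
        duration_s=profile.duration_s, visits=visits,
    )


@dataclass
class EthoProfile:
    """Bout structure of a simulated home-cage event stream.

    ``bout_rate_per_s`` maps stereotypy forms to the Poisson rate of bout
    onsets during (and slightly before) observation blocks. Continuous
    bouts (bar-mouthing) last ``bout_duration_s``; discrete-repetition
    bouts consist of ``n_repeats`` events of ``repeat_duration_s`` each with
    ``repeat_gap_s`` pauses. Durations are fixed so the expected flagged
    proportion is analytic (:func:`expected_flag_probability`).
    ``activity_fraction`` is the target proportion of time spent active,
    generated as an alternating active/inactive renewal process with mean
    active period ``mean_active_s``; 1.0 covers every block with activity.
    """

    bout_rate_per_s: dict[str, float] = field(
        default_factory=lambda: {"bar_mouthing": 0.005}
    )
    bout_duration_s: float = 10.0
    n_repeats: int = 4
    repeat_duration_s: float = 1.0
    repeat_gap_s: float = 1.0
    activity_fraction: float = 1.0
    mean_active_s: float = 60.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        bad = set(self.bout_rate_per_s) - set(STEREOTYPY_FORMS)
        if bad:
            raise ValueError(f"unknown stereotypy forms: {sorted(bad)}")
        if any(r < 0 for r in self.bout_rate_per_s.values()):
            raise ValueError("bout rates must be >= 0")
        if self.bout_duration_s <= 0 or self.repeat_duration_s <= 0:
            raise ValueError("durations must be > 0")
        if not 0.0 <= self.activity_fraction <= 1.0:
            raise ValueError("activity_fraction must be in [0, 1]")

    def bout_span_s(self, form: str) -> float:
        """Total span of one bout of ``form``, start of first to end of last."""
        if form in CONTINUOUS_FORMS:
            return self.bout_duration_s
        return (
            self.n_repeats * self.repeat_duration_s
            + (self.n_repeats - 1) * self.repeat_gap_s
        )


def expected_flag_probability(
    rate_per_s: float, bout_span_s: float, interval_s: float = 15.0
) -> float:
    """Probability a sampling interval is flagged under Poisson bout onsets.

    A bout of span ``d`` overlaps ``[t, t + w)`` iff its onset falls in an
    interval of length ``w + d``, so ``P = 1 - exp(-rate * (w + d))``.
    """
    return 1.0 - math.exp(-rate_per_s * (interval_s + bout_span_s))


def simulate_ethogram(
    profile: EthoProfile, scheme: ObservationScheme
) -> list[BehaviourEvent]:
    """Generate a behaviour event stream over the scheme's observation blocks.

    Bout onsets form per-form Poisson processes over each block extended
    backwards by one bout span (so edge intervals see the stationary
    overlap rate); activity is an alternating renewal process per block.
    Reproducible from ``profile.seed``.
    """
    rng = np.random.default_rng(profile.seed)
    events: list[BehaviourEvent] = []
    blocks = [
        (day * scheme.day_length_s + b0, day * scheme.day_length_s + b0 + scheme.block_length_s)
        for day in range(scheme.days)
        for b0 in sorted(scheme.block_starts_s)
    ]

    for b0, b1 in blocks:
        for form, rate in profile.bout_rate_per_s.items():
            if rate <= 0:
                continue
            span = profile.bout_span_s(form)
            lo = b0 - span
            n = rng.poisson(rate * (b1 - lo))
            onsets = np.sort(rng.uniform(lo, b1, size=n))
            for t in onsets:
                if form in CONTINUOUS_FORMS:
                    events.append(
                        BehaviourEvent(form, float(t), float(t + profile.bout_duration_s))
                    )
                else:
                    for k in range(profile.n_repeats):
                        s = t + k * (profile.repeat_duration_s + profile.repeat_gap_s)
                        events.append(
                            BehaviourEvent(
                                form, float(s), float(s + profile.repeat_duration_s)
                            )
                        )
        # activity renewal process
        a = profile.activity_fraction
        if a >= 1.0:
            events.append(BehaviourEvent("active", b0, b1))
        elif a > 0.0:
            mean_inactive = profile.mean_active_s * (1.0 - a) / a
            t = b0
            active_now = rng.random() < a
            while t < b1:
                dur = rng.exponential(
                    profile.mean_active_s if active_now else mean_inactive
                )
                end = min(t + dur, b1)
                if active_now and end > t:
                    events.append(BehaviourEvent("active", float(t), float(end)))
                t = end
                active_now = not active_now

    events.sort(key=lambda e: (e.start_s, e.behaviour))
    return events
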