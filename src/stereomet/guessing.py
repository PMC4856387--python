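"""Closed-loop controller for the two-choice guessing task.

The task confronts a mouse with two goal compartments (left ``'L'`` and
right ``'R'``). On every trial exactly one compartment is baited, and the
baiting side is drawn adaptively: the probability of baiting *right* equals
the proportion of *left* responses in the subject's recent history, so any
side bias is counteracted and the reward-maximising policy is to choose both
sides equally often. Sequential structure in the resulting choice sequence
(beyond side bias) is then read out by :mod:`stereomet.perseveration`.

The controller here reproduces that baiting rule exactly and runs simulated
sessions against pluggable choice agents (see :mod:`stereomet.synth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "SIDES",
    "Trial",
    "ChoiceSequence",
    "ControllerConfig",
    "bait_probability",
    "next_bait",
    "shaping_block_side",
    "run_session",
]

#: Valid side codes, case-sensitive.
SIDES = ("L", "R")

#: An agent maps (choice history, reward history) to the next side.
Agent = Callable[[Sequence[str], Sequence[bool]], str]


def _check_side(value: str, what: str = "side") -> str:
    if value not in SIDES:
        raise ValueError(f"{what} must be one of {SIDES!r}, got {value!r}")
    return value


@dataclass(frozen=True)
class Trial:
    """One completed trial.

    ``rewarded`` is true iff the chosen compartment was the baited one.
    """

    index: int
    choice: str
    baited: str
    rewarded: bool

    def __post_init__(self) -> None:
        _check_side(self.choice, "choice")
        _check_side(self.baited, "baited")
        if self.rewarded != (self.choice == self.baited):
            raise ValueError(
                f"trial {self.index}: rewarded={self.rewarded} inconsistent with "
                f"choice={self.choice!r}, baited={self.baited!r}"
            )


@dataclass
class ChoiceSequence:
    """Ordered trials of one subject's guessing-task session(s)."""

    subject_id: str
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pos, t in enumerate(self.trials, start=1):
            if t.index != pos:
                raise ValueError(
                    f"subject {self.subject_id}: trial indices must be contiguous "
                    f"1..n; found index {t.index} at position {pos}"
                )

    @property
    def n(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> str:
        """Choice string, e.g. ``'LRRL...'``."""
        return "".join(t.choice for t in self.trials)

    @property
    def rewards(self) -> list[bool]:
        return [t.rewarded for t in self.trials]


@dataclass
class ControllerConfig:
    """Parameters of a simulated session.

    window
        Number of recent trials over which the side bias is measured
        (20 in the live protocol).
    n_trials
        Session length (80 in the live protocol's test phase).
    shaping_block
        Apply the shaping-phase rule that closes a side chosen three times
        in succession. Off for the test phase.
    """

    window: int = 20
    n_trials: int = 80
    seed: Optional[int] = None
    shaping_block: bool = False

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def bait_probability(history: Sequence[str], window: int = 20) -> float:
    """Probability that the *right* compartment is baited next.

    Equals the proportion of left responses in the most recent ``window``
    trials; with fewer than ``window`` previous trials, all of them are used
    (the live controller computed the bias from all previous trials during
    trials 1-19). An empty history gives the symmetric 0.5.
    """
    if not history:
        return 0.5
    span = history if len(history) < window else history[-window:]
    n_left = sum(1 for c in span if _check_side(c, "history entry") == "L")
    return n_left / len(span)


def next_bait(
    history: Sequence[str], config: ControllerConfig, rng: np.random.Generator
) -> str:
    """Draw the side to bait, consuming exactly one uniform variate."""
    p_right = bait_probability(history, config.window)
    return "R" if rng.random() < p_right else "L"


def shaping_block_side(history: Sequence[str]) -> Optional[str]:
    """Side to close on the next shaping trial, or ``None``.

    A side is closed when the subject chose it on each of the last three
    trials, preventing the shaping phase from training a side preference.
    """
    if len(history) < 3:
        return None
    last3 = set(history[-3:])
    if len(last3) == 1:
        return last3.pop()
    return None


def run_session(agent: Agent, config: ControllerConfig) -> ChoiceSequence:
    """Simulate one session of ``config.n_trials`` trials.

    Each trial the baited side is drawn *before* the agent chooses (the live
    apparatus baits goalpots pre-trial), and the agent never observes it.

    With ``shaping_block`` enabled the session emulates the shaping phase
    instead: both goalpots are baited (every completed trial is rewarded,
    and the recorded baited side equals the choice), and a side chosen three
    times in succession is closed on the next trial, forcing the opposite
    choice as the closed guillotine door would. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    choices: list[str] = []
    rewards: list[bool] = []
    trials: list[Trial] = []
    for i in range(1, config.n_trials + 1):
        baited = None if config.shaping_block else next_bait(choices, config, rng)
        choice = agent(tuple(choices), tuple(rewards))
        if choice not in SIDES:
            raise ValueError(
                f"agent returned {choice!r} on trial {i}; expected one of {SIDES!r}"
            )
        if config.shaping_block:
            blocked = shaping_block_side(choices)
            if blocked is not None and choice == blocked:
                choice = "L" if blocked == "R" else "R"
            baited = choice
        rewarded = choice == baited
        trials.append(Trial(index=i, choice=choice, baited=baited, rewarded=rewarded))
        choices.append(choice)
        rewards.append(rewarded)
    return ChoiceSequence(subject_id="sim", trials=trials)
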