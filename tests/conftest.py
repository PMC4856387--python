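import itertools

import numpy as np
import pytest

from stereomet import ArmVisit, ArmVisitLog, DEFAULT_TEST_ROLES


@pytest.fixture(scope="session")
def test_roles():
    return DEFAULT_TEST_ROLES


@pytest.fixture(scope="session")
def make_log():
    """Build an ArmVisitLog with one visit per requested role-time pair.

    Visits are laid back to back from t=0 in arms 1 (positive), 5
    (negative), 3 (near_positive), 4 (near_negative).
    """
    role_arm = {"positive": 1, "negative": 5, "near_positive": 3, "near_negative": 4}

    def _make(times: dict[str, float], duration_s: float = 600.0,
              subject_id: str = "s1", session_id: str = "test") -> ArmVisitLog:
        visits, t = [], 0.0
        for role, dur in times.items():
            if dur > 0:
                visits.append(ArmVisit(arm_id=role_arm[role], entry_s=t, exit_s=t + dur))
                t += dur
        return ArmVisitLog(subject_id=subject_id, session_id=session_id,
                           duration_s=duration_s, visits=visits)

    return _make


def brute_force_markov_chi_sq(s: str, order: int = 3) -> float:
    """Independent oracle: explicit 2^order x 2 contingency enumeration.

    Builds the full context table over all 2^order contexts, computes
    expected cell counts from the whole-sequence side proportions, and sums
    (O - E)^2 / E over cells with E > 0.
    """
    contexts = ["".join(c) for c in itertools.product("LR", repeat=order)]
    table = {c: {"L": 0, "R": 0} for c in contexts}
    for i in range(len(s) - order):
        table[s[i:i + order]][s[i + order]] += 1
    m = {"L": s.count("L") / len(s), "R": s.count("R") / len(s)}
    chi = 0.0
    for c in contexts:
        n_ctx = table[c]["L"] + table[c]["R"]
        if n_ctx == 0:
            continue
        for x in "LR":
            e = n_ctx * m[x]
            if e > 0:
                chi += (table[c][x] - e) ** 2 / e
    return chi


def fair_choice_strings(n_sequences: int, n_trials: int, seed: int) -> list[str]:
    """I.i.d. fair L/R sequences, vectorised."""
    rng = np.random.default_rng(seed)
    draws = rng.random((n_sequences, n_trials)) < 0.5
    return ["".join("R" if b else "L" for b in row) for row in draws]
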