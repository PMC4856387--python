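"""Recurrent-perseveration metrics for binary choice sequences.

Recurrent perseveration — inappropriate repetition of responses — shows up
in a two-choice task as *sequential dependence*: the next choice is
predictable from recent choices, whether as runs of repetitions or as rigid
alternation. Two complementary read-outs are computed here.

1. A Markov-chain test of sequential independence. For each length-``k``
   context (default ``k = 3``) the observed distribution of the following
   choice is compared against the expectation under independence, and the
   summed chi-square statistic is converted to a tail probability *p* (the
   probability that the sequence is sequentially independent). The
   perseveration score is ``logit(P)`` with ``P = 1 - p``: high for any
   strongly patterned sequence, near ``logit(0.5)``-ish noise for random
   ones.

2. Tetragram counts: the sequence is cut into overlapping windows of four
   consecutive choices (an 80-trial sequence gives 77 windows over the 16
   possible configurations; a random strategy spreads them uniformly,
   77/16 = 4.8 each). Pure repetitions (``LLLL``, ``RRRR``) and pure
   alternations (``LRLR``, ``RLRL``) are the patterned extremes.

Side bias (proportion of right choices) is reported separately: the null
expectation of the Markov test preserves the sequence's marginal side
proportions, so the statistic detects sequential structure *beyond* bias.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Union

from scipy.stats import chi2

from .guessing import SIDES, ChoiceSequence

__all__ = [
    "TetragramTable",
    "PerseverationResult",
    "tetragram_counts",
    "pure_repetitions",
    "pure_alternations",
    "side_bias",
    "correct_choice_proportion",
    "markov_perseveration",
]

#: All 16 length-4 L/R configurations in lexicographic order.
TETRAGRAMS = tuple("".join(w) for w in itertools.product(SIDES, repeat=4))

PURE_REPETITIONS = ("LLLL", "RRRR")
PURE_ALTERNATIONS = ("LRLR", "RLRL")

SeqLike = Union[ChoiceSequence, str]


def _choice_string(seq: SeqLike) -> str:
    s = seq.choices if isinstance(seq, ChoiceSequence) else seq
    bad = set(s) - set(SIDES)
    if bad:
        raise ValueError(f"choice string contains non-side characters {sorted(bad)!r}")
    return s


@dataclass
class TetragramTable:
    """Counts of every overlapping 4-choice window of one sequence."""

    counts: dict[str, int]
    n_windows: int


@dataclass
class PerseverationResult:
    """Outcome of the Markov-chain sequential-independence test.

    Attributes
    ----------
    chi_sq, df, p
        Summed chi-square statistic, its degrees of freedom, and the
        upper-tail probability of sequential independence.
    P
        ``1 - p``; 1 for a completely perseverant (fully predictable)
        sequence.
    logitP
        ``ln(Pc / (1 - Pc))`` where ``Pc`` is ``P`` clamped away from 0 and
        1; the primary perseveration score.
    clamped
        True when the clamp was binding (degenerate sequences).
    order
        Markov order ``k`` used for the contexts.
    """

    chi_sq: float
    df: int
    p: float
    P: float
    logitP: float
    clamped: bool
    order: int


def tetragram_counts(seq: SeqLike) -> TetragramTable:
    """Count every overlapping window of four consecutive choices.

    All 16 configurations are present in the result (zero-filled); the
    counts sum to ``n - 3``.
    """
    s = _choice_string(seq)
    if len(s) < 4:
        raise ValueError(f"need at least 4 trials for tetragrams, got {len(s)}")
    counts = dict.fromkeys(TETRAGRAMS, 0)
    for i in range(len(s) - 3):
        counts[s[i : i + 4]] += 1
    return TetragramTable(counts=counts, n_windows=len(s) - 3)


def pure_repetitions(table: TetragramTable) -> int:
    """``LLLL`` + ``RRRR`` window count."""
    return sum(table.counts[k] for k in PURE_REPETITIONS)


def pure_alternations(table: TetragramTable) -> int:
    """``LRLR`` + ``RLRL`` window count."""
    return sum(table.counts[k] for k in PURE_ALTERNATIONS)


def side_bias(seq: SeqLike) -> float:
    """Proportion of right choices."""
    s = _choice_string(seq)
    if not s:
        raise ValueError("empty sequence")
    return s.count("R") / len(s)


def correct_choice_proportion(seq: ChoiceSequence) -> float:
    """Proportion of rewarded trials (choice matched the baited side)."""
    if seq.n == 0:
        raise ValueError("empty sequence")
    return sum(seq.rewards) / seq.n


def markov_perseveration(
    seq: SeqLike,
    order: int = 3,
    null: str = "marginal",
    eps: float = 1e-12,
) -> PerseverationResult:
    """Test a choice sequence for sequential dependence at Markov order ``k``.

    For every length-``order`` context occurring in the sequence, the
    observed counts of the next choice are compared with expected counts
    ``E(context, x) = n(context) * m(x)``. Under ``null='marginal'`` (the
    default) ``m(x)`` is the proportion of choice ``x`` over the whole
    sequence, so plain side bias contributes nothing and only structure
    beyond it is detected; ``null='fair'`` uses ``m(x) = 0.5``.

    The statistic sums ``(O - E)^2 / E`` over cells with ``E > 0``; degrees
    of freedom count one per occurring context, minus one under the
    marginal null for the side proportion estimated from the same sequence
    (testing order 0 against order ``k`` on a binary alphabet gives
    ``2^k - 1`` when every context occurs; the subtraction keeps the test's
    null rejection rate near its nominal level), floored at 1. ``p`` is the
    chi-square upper-tail probability, ``P = 1 - p``, and ``logitP`` is
    computed after
    clamping ``P`` into ``[eps, 1 - eps]`` (a fully one-sided sequence has
    ``chi_sq = 0``, ``p = 1``, ``P = 0`` and is flagged ``clamped``).
    """
    s = _choice_string(seq)
    if order < 1:
        raise ValueError("order must be >= 1")
    if null not in ("marginal", "fair"):
        raise ValueError(f"null must be 'marginal' or 'fair', got {null!r}")
    if len(s) < order + 1:
        raise ValueError(
            f"need at least order+1 = {order + 1} trials, got {len(s)}"
        )

    if null == "marginal":
        marg = {x: s.count(x) / len(s) for x in SIDES}
    else:
        marg = {x: 0.5 for x in SIDES}

    # context -> observed counts of the next choice
    obs: dict[str, dict[str, int]] = {}
    for i in range(len(s) - order):
        ctx = s[i : i + order]
        nxt = s[i + order]
        obs.setdefault(ctx, {x: 0 for x in SIDES})[nxt] += 1

    chi_sq = 0.0
    for ctx, row in obs.items():
        n_ctx = sum(row.values())
        for x in SIDES:
            e = n_ctx * marg[x]
            if e > 0:
                chi_sq += (row[x] - e) ** 2 / e
    df = len(obs) * (len(SIDES) - 1)
    if null == "marginal":
        df -= 1  # side proportion estimated from the sequence itself
    df = max(df, 1)

    p = float(chi2.sf(chi_sq, df))
    P = 1.0 - p
    Pc = min(max(P, eps), 1.0 - eps)
    return PerseverationResult(
        chi_sq=chi_sq,
        df=df,
        p=p,
        P=P,
        logitP=math.log(Pc / (1.0 - Pc)),
        clamped=Pc != P,
        order=order,
    )
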