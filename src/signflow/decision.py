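"""Fusing the two per-orientation decision scores into one directionality call.

A protein pair (A, B) is scored twice, once per putative direction. The two
signed margins f(A→B) and f(B→A) are combined into a single call:

* opposite signs — the orientation scored positive wins outright;
* both non-negative — the larger score wins if the scores differ by more
  than ``epsilon``, otherwise the pair is called bidirectional;
* both negative — neither orientation looks like a verified direction, but
  the one with the smaller magnitude is the "less incredible" and wins if
  the magnitudes differ by more than ``epsilon``; otherwise the model cannot
  commit and the call is undetermined.

Exact zeros are treated as non-negative. Equal non-negative scores are
bidirectional even at ``epsilon = 0``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, List

__all__ = ["DirectionCall", "DecisionPolicy", "fuse", "fuse_bag", "fuse_bags", "mirror_call"]


class DirectionCall(enum.Enum):
    """Outcome of fusing the two orientation scores of one pair."""

    A_TO_B = "A->B"
    B_TO_A = "B->A"
    BIDIRECTIONAL = "<->"
    UNDETERMINED = "?"

    @property
    def token(self) -> str:
        """The stable text token used in prediction tables."""
        return self.value

    @classmethod
    def from_token(cls, token: str) -> "DirectionCall":
        for call in cls:
            if call.value == token:
                return call
        raise ValueError(f"unknown direction-call token: {token!r}")


@dataclass(frozen=True)
class DecisionPolicy:
    """Threshold on score differences separating directed from ambiguous calls.

    epsilon : float
        Non-negative. Score (or, for doubly-negative pairs, magnitude)
        differences at or below ``epsilon`` are considered ties.
    """

    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if not (self.epsilon >= 0.0):
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")


def fuse(f_ab: float, f_ba: float, policy: DecisionPolicy) -> DirectionCall:
    """Combine the two orientation scores of a pair into a direction call."""
    if math.isnan(f_ab) or math.isnan(f_ba):
        raise ValueError(f"NaN decision score: f_ab={f_ab}, f_ba={f_ba}")
    eps = policy.epsilon
    ab_nonneg = f_ab >= 0.0
    ba_nonneg = f_ba >= 0.0
    if ab_nonneg and not ba_nonneg:
        return DirectionCall.A_TO_B
    if ba_nonneg and not ab_nonneg:
        return DirectionCall.B_TO_A
    if ab_nonneg and ba_nonneg:
        if f_ab == f_ba:
            return DirectionCall.BIDIRECTIONAL
        if abs(f_ab - f_ba) > eps:
            return DirectionCall.A_TO_B if f_ab > f_ba else DirectionCall.B_TO_A
        return DirectionCall.BIDIRECTIONAL
    # both strictly negative: prefer the smaller magnitude
    if abs(abs(f_ab) - abs(f_ba)) > eps:
        return DirectionCall.A_TO_B if abs(f_ab) < abs(f_ba) else DirectionCall.B_TO_A
    return DirectionCall.UNDETERMINED


def mirror_call(call: DirectionCall) -> DirectionCall:
    """The call obtained when the two proteins of the pair swap roles."""
    if call is DirectionCall.A_TO_B:
        return DirectionCall.B_TO_A
    if call is DirectionCall.B_TO_A:
        return DirectionCall.A_TO_B
    return call


def fuse_bag(bag, model, policy: DecisionPolicy):
    """Score both instances of ``bag`` with ``model`` and populate its call.

    Returns the same bag with ``score_fwd``, ``score_rev`` and ``call`` set.
    """
    from .classifier import decision_score

    bag.score_fwd = float(decision_score(model, bag.fwd))
    bag.score_rev = float(decision_score(model, bag.rev))
    bag.call = fuse(bag.score_fwd, bag.score_rev, policy)
    return bag


def fuse_bags(bags: Iterable, model, policy: DecisionPolicy) -> List:
    """Vectorised ``fuse_bag`` over a batch of encodable bags."""
    from .classifier import decision_scores

    bags = list(bags)
    if not bags:
        return bags
    instances = [b.fwd for b in bags] + [b.rev for b in bags]
    scores = decision_scores(model, instances)
    n = len(bags)
    for i, bag in enumerate(bags):
        bag.score_fwd = float(scores[i])
        bag.score_rev = float(scores[n + i])
        bag.call = fuse(bag.score_fwd, bag.score_rev, policy)
    return bags
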