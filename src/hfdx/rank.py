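"""Rank-based choice among candidate rule-generation algorithms.

Candidates are compared on three axes: held-out accuracy (higher is
better) and the complexity of the extracted knowledge — number of rules
and number of distinct attributes involved (fewer is better for a
knowledge base physicians must review).  Each axis is min-max normalized
across the candidate set and combined as

    rank = w_a * acc~  +  w_r * (1 - rules~)  +  w_t * (1 - attrs~)

with default weights (0.6, 0.2, 0.2).  When an axis is constant across
candidates its normalized value is taken as 1 for accuracy and 0 for the
complexity counts, so a lone candidate scores 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import HfdxError
from .cart import InductionParams, cross_val_accuracy, induce_cart
from .schema import AttributeSchema, PatientRecord

__all__ = ["RankScore", "rank_algorithms", "score_cart_candidate"]


@dataclass(frozen=True)
class RankScore:
    algorithm_name: str
    accuracy: float  # percent
    n_rules: int
    n_attributes: int
    rank_value: float = 0.0


def _minmax(values: Sequence[float], degenerate: float) -> list[float]:
    lo, hi = min(values), max(values)
    if hi == lo:
        return [degenerate] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def rank_algorithms(candidates: Sequence[RankScore],
                    weights: tuple[float, float, float] = (0.6, 0.2, 0.2)) -> list[RankScore]:
    """Score and sort candidates by rank_value (descending; ties broken by
    accuracy, then name).  Invariant under candidate reordering."""
    if not candidates:
        raise HfdxError("rank_algorithms needs at least one candidate")
    for c in candidates:
        if not (0.0 <= c.accuracy <= 100.0):
            raise HfdxError(f"candidate {c.algorithm_name!r}: accuracy must be in [0, 100]")
        if c.n_rules < 1 or c.n_attributes < 1:
            raise HfdxError(f"candidate {c.algorithm_name!r}: rule/attribute counts must be positive")
    w_a, w_r, w_t = weights
    acc = _minmax([c.accuracy for c in candidates], degenerate=1.0)
    rules = _minmax([float(c.n_rules) for c in candidates], degenerate=0.0)
    attrs = _minmax([float(c.n_attributes) for c in candidates], degenerate=0.0)
    scored = [
        RankScore(c.algorithm_name, c.accuracy, c.n_rules, c.n_attributes,
                  rank_value=w_a * a + w_r * (1.0 - r) + w_t * (1.0 - t))
        for c, a, r, t in zip(candidates, acc, rules, attrs)
    ]
    return sorted(scored, key=lambda s: (-s.rank_value, -s.accuracy, s.algorithm_name))


def score_cart_candidate(records: Sequence[PatientRecord],
                         params: Optional[InductionParams] = None,
                         schema: Optional[AttributeSchema] = None,
                         k: int = 5,
                         name: str = "CART") -> RankScore:
    """Build the (accuracy, n_rules, n_attributes) inputs for the native
    CART learner: stratified k-fold accuracy plus the complexity of the
    tree induced on the full training set."""
    params = params or InductionParams()
    accuracy = cross_val_accuracy(records, params, k=k, schema=schema)
    tree = induce_cart(records, params, schema)
    attrs = {n.attribute for n in tree.walk() if not n.is_leaf}
    return RankScore(name, accuracy, tree.n_leaves, max(len(attrs), 1))
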