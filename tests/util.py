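"""Shared helpers: seeded random trees and records for property tests."""

from __future__ import annotations

import numpy as np

from hfdx import (Branch, DecisionNode, DecisionTree, Diagnosis, Interval,
                  PatientRecord, default_schema)

INF = float("inf")

#: a small attribute pool mixing continuous and binary kinds
POOL = ("lvef", "lavi", "nt_probnp", "male", "abnormal_ecg", "hf_symptoms_signs")


def random_tree(rng: np.random.Generator, max_depth: int = 4,
                attrs=POOL, na_route_p: float = 0.3,
                tree_id: str = "random") -> DecisionTree:
    """A random structurally valid tree: interval branches tile each
    continuous attribute's valid range; binary nodes get both values."""
    schema = default_schema()
    counter = [0]

    def leaf() -> DecisionNode:
        counter[0] += 1
        return DecisionNode(f"n{counter[0]}", "expert",
                            diagnosis=list(Diagnosis)[rng.integers(4)])

    def grow(depth: int) -> DecisionNode:
        if depth >= max_depth or rng.random() < 0.3 + 0.2 * depth:
            return leaf()
        counter[0] += 1
        node_id = f"n{counter[0]}"
        name = attrs[rng.integers(len(attrs))]
        attr = schema[name]
        if attr.is_binary:
            branches = [Branch(grow(depth + 1), value=False),
                        Branch(grow(depth + 1), value=True)]
        else:
            lo, hi = attr.valid_range
            k = int(rng.integers(1, 3))
            cuts = sorted(set(float(np.round(rng.uniform(lo + 0.05 * (hi - lo),
                                                         hi - 0.05 * (hi - lo)), 1))
                              for _ in range(k)))
            bounds = [-INF] + cuts + [INF]
            branches = [Branch(grow(depth + 1),
                               interval=Interval(a, b, a != -INF, False))
                        for a, b in zip(bounds[:-1], bounds[1:])]
        na_route = int(rng.integers(len(branches))) if rng.random() < na_route_p else None
        return DecisionNode(node_id, "expert", attribute=name,
                            branches=branches, na_route=na_route)

    return DecisionTree(tree_id, grow(0))


def oracle_best_split(records, attrs, schema=None):
    """Independent brute-force split search: enumerate every
    (attribute, threshold) candidate, merge Missing records into the
    majority side (tie: low), keep the first maximum of the weighted Gini
    decrease in (schema-order attribute, ascending threshold) scan order.
    Returns (attribute, threshold, decrease, na_side) or None."""
    schema = schema or default_schema()

    def gini(ls):
        n = len(ls)
        return 1.0 - sum((ls.count(d) / n) ** 2 for d in Diagnosis) if n else 0.0

    labels = [r.gold_diagnosis for r in records]
    parent = gini(labels)
    n = len(records)
    best = None
    for name in schema.names:
        if name not in attrs:
            continue
        pairs = [(r.get(name), r.gold_diagnosis) for r in records]
        present = [(v, g) for v, g in pairs if v is not None]
        miss = [g for v, g in pairs if v is None]
        if len(present) < 2:
            continue
        if schema[name].is_binary:
            cands = [None]
        else:
            uniq = sorted(set(float(v) for v, _ in present))
            if len(uniq) < 2:
                continue
            cands = [(a + b) / 2.0 for a, b in zip(uniq, uniq[1:])]
        for t in cands:
            if t is None:
                low = [g for v, g in present if not bool(v)]
                high = [g for v, g in present if bool(v)]
            else:
                low = [g for v, g in present if float(v) < t]
                high = [g for v, g in present if float(v) >= t]
            na_side = "low" if len(low) >= len(high) else "high"
            if na_side == "low":
                low = low + miss
            else:
                high = high + miss
            if not low or not high:
                continue
            dec = parent - (len(low) * gini(low) + len(high) * gini(high)) / n
            if best is None or dec > best[2] + 1e-12:
                best = (name, t, dec, na_side)
    if best is None or best[2] <= 1e-12:
        return None
    return best


def random_records(rng: np.random.Generator, n: int, missing_rate: float = 0.0,
                   with_gold: bool = True) -> list[PatientRecord]:
    """Uniformly random records over the schema's valid ranges."""
    schema = default_schema()
    out = []
    for i in range(n):
        values = {}
        for attr in schema:
            if rng.random() < missing_rate:
                values[attr.name] = None
            elif attr.is_binary:
                values[attr.name] = bool(rng.random() < 0.5)
            else:
                lo, hi = attr.valid_range
                values[attr.name] = float(np.round(rng.uniform(lo, hi), 1))
        gold = list(Diagnosis)[rng.integers(4)] if with_gold else None
        out.append(PatientRecord(f"r{i}", values, gold))
    return out
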