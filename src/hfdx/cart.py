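"""CART-style decision-tree induction with native Missing-value handling.

Greedy binary recursive partitioning on the Gini impurity.  Continuous
attributes are split at midpoints between consecutive distinct observed
values; binary attributes split on false/true.  Records Missing the split
attribute are routed to the side carrying the larger number of observed
records (tie: the low/false side); the chosen side is recorded on the
node as an explicit ``na_route`` so induced trees are total — they never
return Uncovered — and compose cleanly with the hybridizer's
Not-Available path semantics.  No surrogate splits, no pruning beyond the
stopping rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, HfdxError
from .schema import AttributeSchema, Diagnosis, PatientRecord, default_schema
from .tree import Branch, DecisionNode, DecisionTree, Interval

__all__ = [
    "InductionParams",
    "gini_impurity",
    "best_split",
    "Split",
    "induce_cart",
    "rank_features",
    "cross_val_accuracy",
]

INF = float("inf")
_LABELS = list(Diagnosis)
_EPS = 1e-12


@dataclass(frozen=True)
class InductionParams:
    """Hyper-parameters of the induction.

    Defaults: depth 6, at least 5 records per leaf, any positive impurity
    decrease accepted.  ``seed`` only feeds fold assignment in
    cross-validation; induction itself is deterministic.
    """

    max_depth: int = 6
    min_samples_leaf: int = 5
    min_impurity_decrease: float = 0.0
    seed: int = 0

    def validate(self) -> "InductionParams":
        if self.max_depth < 0:
            raise ConfigError("max_depth must be >= 0")
        if self.min_samples_leaf < 1:
            raise ConfigError("min_samples_leaf must be >= 1")
        if self.min_impurity_decrease < 0:
            raise ConfigError("min_impurity_decrease must be >= 0")
        return self


def gini_impurity(labels: Sequence[Diagnosis]) -> float:
    """Gini impurity 1 - sum(p_k^2) of a label multiset.

    0 for a pure set; 0.75 at the uniform mixture over the four labels.
    """
    labels = list(labels)
    if not labels:
        raise HfdxError("gini_impurity of an empty label set is undefined")
    counts = np.array([sum(1 for l in labels if l is d) for d in _LABELS], dtype=float)
    p = counts / counts.sum()
    return float(1.0 - (p ** 2).sum())


def _gini_codes(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    counts = np.bincount(y, minlength=len(_LABELS)).astype(float)
    p = counts / y.size
    return float(1.0 - (p ** 2).sum())


def _records_to_arrays(records: Sequence[PatientRecord], schema: AttributeSchema,
                       require_gold: bool = True) -> tuple[np.ndarray, np.ndarray]:
    n, p = len(records), len(schema)
    X = np.full((n, p), np.nan)
    y = np.zeros(n, dtype=int)
    for i, rec in enumerate(records):
        for j, attr in enumerate(schema):
            v = rec.values.get(attr.name)
            if v is None:
                continue
            X[i, j] = float(bool(v)) if attr.is_binary else float(v)
        if rec.gold_diagnosis is None:
            if require_gold:
                raise HfdxError(f"record {rec.patient_id!r} has no gold diagnosis")
        else:
            y[i] = _LABELS.index(rec.gold_diagnosis)
    return X, y


@dataclass(frozen=True)
class Split:
    """A chosen split: ``threshold`` is None for binary attributes (the
    low side is then false); ``na_side`` says where Missing values go."""

    attribute: str
    threshold: Optional[float]
    decrease: float
    na_side: str  # "low" | "high"


def _col_best_split(col: np.ndarray, y: np.ndarray, is_binary: bool,
                    min_samples_leaf: int, parent_gini: float):
    """Best (threshold, decrease, na_side) on one column, or None."""
    present = ~np.isnan(col)
    vals = col[present]
    if vals.size < 2:
        return None
    y_p, y_m = y[present], y[~present]
    n = y.size
    if is_binary:
        thresholds = [0.5]
    else:
        uniq = np.unique(vals)
        if uniq.size < 2:
            return None
        thresholds = ((uniq[:-1] + uniq[1:]) / 2.0).tolist()
    best = None
    for t in thresholds:
        low_mask = vals < t
        n_low, n_high = int(low_mask.sum()), int((~low_mask).sum())
        na_side = "low" if n_low >= n_high else "high"
        y_low = y_p[low_mask]
        y_high = y_p[~low_mask]
        if na_side == "low":
            y_low = np.concatenate([y_low, y_m])
        else:
            y_high = np.concatenate([y_high, y_m])
        if y_low.size < min_samples_leaf or y_high.size < min_samples_leaf:
            continue
        child = (y_low.size * _gini_codes(y_low) + y_high.size * _gini_codes(y_high)) / n
        dec = parent_gini - child
        if best is None or dec > best[1] + _EPS:
            best = (None if is_binary else float(t), dec, na_side)
    return best


def _best_split_arrays(X: np.ndarray, y: np.ndarray, schema: AttributeSchema,
                       attributes: Sequence[str], min_samples_leaf: int) -> Optional[Split]:
    parent = _gini_codes(y)
    best: Optional[Split] = None
    for name in sorted(attributes, key=schema.index):  # schema order breaks ties
        j = schema.index(name)
        cand = _col_best_split(X[:, j], y, schema[name].is_binary, min_samples_leaf, parent)
        if cand is None:
            continue
        t, dec, na_side = cand
        if best is None or dec > best.decrease + _EPS:
            best = Split(name, t, dec, na_side)
        # ties: keep the earlier schema attribute / smaller threshold,
        # which the scan order already guarantees
    return best


def best_split(records: Sequence[PatientRecord],
               attributes: Optional[Sequence[str]] = None,
               schema: Optional[AttributeSchema] = None,
               min_samples_leaf: int = 1) -> Optional[Split]:
    """The (attribute, threshold) pair maximizing the weighted Gini
    decrease, or None when no admissible split exists.

    Ties are broken toward the earlier schema attribute, then the smaller
    threshold.  Missing values are routed to the majority-weight side.
    """
    if len(records) < 2:
        raise HfdxError("best_split needs at least two records")
    schema = schema or default_schema()
    attributes = list(attributes) if attributes is not None else list(schema.names)
    X, y = _records_to_arrays(records, schema)
    split = _best_split_arrays(X, y, schema, attributes, min_samples_leaf)
    if split is not None and split.decrease <= _EPS:
        return None
    return split


def _majority(y: np.ndarray) -> Diagnosis:
    counts = np.bincount(y, minlength=len(_LABELS))
    return _LABELS[int(np.argmax(counts))]  # argmax tie -> declaration order


def _grow(X: np.ndarray, y: np.ndarray, idx: np.ndarray, depth: int,
          params: InductionParams, schema: AttributeSchema,
          attributes: Sequence[str], counter: list[int],
          importance: Optional[dict[str, float]], n_total: int,
          provenance: str) -> DecisionNode:
    node_id = f"pm{counter[0]}"
    counter[0] += 1
    ysub = y[idx]
    leaf = DecisionNode(node_id, provenance, diagnosis=_majority(ysub))
    if depth >= params.max_depth or idx.size < 2 * params.min_samples_leaf or _gini_codes(ysub) == 0.0:
        return leaf
    split = _best_split_arrays(X[idx], ysub, schema, attributes, params.min_samples_leaf)
    if split is None or split.decrease <= max(params.min_impurity_decrease, _EPS):
        return leaf
    if importance is not None:
        importance[split.attribute] = importance.get(split.attribute, 0.0) + \
            (idx.size / n_total) * split.decrease
    j = schema.index(split.attribute)
    col = X[idx, j]
    missing = np.isnan(col)
    if split.threshold is None:
        low = col == 0.0
    else:
        low = col < split.threshold
    high = ~low & ~missing
    low &= ~missing
    if split.na_side == "low":
        low |= missing
    else:
        high |= missing
    kid_low = _grow(X, y, idx[low], depth + 1, params, schema, attributes,
                    counter, importance, n_total, provenance)
    kid_high = _grow(X, y, idx[high], depth + 1, params, schema, attributes,
                     counter, importance, n_total, provenance)
    if split.threshold is None:
        branches = [Branch(kid_low, value=False), Branch(kid_high, value=True)]
    else:
        branches = [Branch(kid_low, interval=Interval(-INF, split.threshold, False, False)),
                    Branch(kid_high, interval=Interval(split.threshold, INF, True, False))]
    return DecisionNode(node_id, provenance, attribute=split.attribute, branches=branches,
                        na_route=0 if split.na_side == "low" else 1)


def induce_cart(records: Sequence[PatientRecord],
                params: Optional[InductionParams] = None,
                schema: Optional[AttributeSchema] = None,
                attributes: Optional[Sequence[str]] = None,
                tree_id: str = "pm-cart",
                provenance: str = "learned") -> DecisionTree:
    """Induce a decision tree from gold-labeled records."""
    if not records:
        raise HfdxError("cannot induce a tree from an empty training set")
    params = (params or InductionParams()).validate()
    schema = schema or default_schema()
    attributes = list(attributes) if attributes is not None else list(schema.names)
    X, y = _records_to_arrays(records, schema)
    root = _grow(X, y, np.arange(len(records)), 0, params, schema, attributes,
                 [0], None, len(records), provenance)
    return DecisionTree(tree_id, root)


def rank_features(records: Sequence[PatientRecord],
                  schema: Optional[AttributeSchema] = None,
                  params: Optional[InductionParams] = None) -> list[tuple[str, float]]:
    """Gini-based attribute importances from a fully grown tree.

    Importance of an attribute is the total node-weighted impurity
    decrease it contributes, normalized to sum to 1; attributes never
    split on score 0.  A single-class input yields all zeros in schema
    order.
    """
    if len(records) < 2:
        raise HfdxError("rank_features needs at least two records")
    schema = schema or default_schema()
    params = params or InductionParams(max_depth=64, min_samples_leaf=1,
                                       min_impurity_decrease=0.0)
    X, y = _records_to_arrays(records, schema)
    importance: dict[str, float] = {}
    _grow(X, y, np.arange(len(records)), 0, params.validate(), schema,
          list(schema.names), [0], importance, len(records), "learned")
    total = sum(importance.values())
    scores = {name: (importance.get(name, 0.0) / total if total > 0 else 0.0)
              for name in schema.names}
    return sorted(scores.items(), key=lambda kv: (-kv[1], schema.index(kv[0])))


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment per record, stratified by label."""
    rng = np.random.default_rng(seed)
    fold = np.zeros(y.size, dtype=int)
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def cross_val_accuracy(records: Sequence[PatientRecord],
                       params: Optional[InductionParams] = None,
                       k: int = 5,
                       schema: Optional[AttributeSchema] = None) -> float:
    """Stratified k-fold cross-validated accuracy, in percent.

    Induced trees are total (na-routing), so every held-out record gets a
    prediction.
    """
    from .tree import diagnose  # local import to avoid a cycle at module load

    params = (params or InductionParams()).validate()
    schema = schema or default_schema()
    if len(records) < k:
        raise HfdxError(f"need at least k={k} records for {k}-fold cross-validation")
    _, y = _records_to_arrays(records, schema)
    folds = _stratified_folds(y, k, params.seed)
    correct = 0
    for f in range(k):
        test = [r for r, g in zip(records, folds) if g == f]
        train = [r for r, g in zip(records, folds) if g != f]
        if not test or not train:
            continue
        tree = induce_cart(train, params, schema)
        for rec in test:
            trace = diagnose(tree, rec, schema)
            if trace.outcome is rec.gold_diagnosis:
                correct += 1
    return 100.0 * correct / len(records)
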