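"""Hybridization of expert and machine-learned knowledge models.

The expert model (CKM) is authoritative wherever it reaches a decision,
but it typically lacks paths for Missing values — a real cohort always
has records the CKM cannot cover.  Hybridization measures that coverage
gap, then grafts learned subtrees onto every failure point: a dedicated
Not-Available branch where traversal died on a Missing value, and a
domain-gap branch where a value matched no branch.  Each grafted subtree
is re-fit (with the same CART procedure that built the prediction model)
on exactly the uncovered sub-population reaching that point, so it
reflects the conditional distribution there rather than the whole
cohort.  Pre-existing expert nodes are never altered: every record the
CKM covered receives the identical diagnosis from the refined model
(R-CKM), and coverage can only increase.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cart import InductionParams, induce_cart
from .errors import HybridizationError
from .schema import AttributeSchema, Diagnosis, PatientRecord, default_schema
from .tree import (Branch, DecisionNode, DecisionTree, Interval, assert_valid,
                   diagnose)

__all__ = ["UncoveredCase", "CoverageReport", "coverage", "hybridize"]


@dataclass(frozen=True)
class UncoveredCase:
    patient_id: str
    node_id: str
    attribute: str
    reason: str  # "missing" | "gap"


@dataclass
class CoverageReport:
    """Which records a knowledge model can decide.

    ``coverage`` is n_covered / n_records, defined as 1.0 on an empty
    record list (vacuous coverage)."""

    n_records: int
    n_covered: int
    uncovered: list[UncoveredCase] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        return 1.0 if self.n_records == 0 else self.n_covered / self.n_records


def coverage(tree: DecisionTree, records: Sequence[PatientRecord],
             schema: Optional[AttributeSchema] = None) -> CoverageReport:
    """Fraction of records for which *tree* reaches a leaf, with the
    failure node and attribute for every uncovered record."""
    schema = schema or default_schema()
    uncovered = []
    for rec in records:
        trace = diagnose(tree, rec, schema)
        if not trace.is_covered:
            uncovered.append(UncoveredCase(rec.patient_id, trace.failure_node,
                                           trace.failure_attribute, trace.failure_reason))
    return CoverageReport(len(records), len(records) - len(uncovered), uncovered)


def _relabel_grafted(node: DecisionNode, counter: list[int]) -> None:
    node.node_id = f"g{counter[0]}"
    counter[0] += 1
    node.provenance = "grafted"
    for b in node.branches:
        _relabel_grafted(b.child, counter)
    if node.na_child is not None:
        _relabel_grafted(node.na_child, counter)


def _fit_graft(subpop: Sequence[PatientRecord], pm: DecisionTree,
               schema: AttributeSchema, params: InductionParams,
               counter: list[int]) -> DecisionNode:
    """A learned subtree for one uncovered sub-population.

    Labels come from the gold diagnosis when present, else from dropping
    the record down the prediction model.  Sub-populations too small to
    support a split (or with no usable labels at all) get a
    majority-class leaf — NoHF when empty.
    """
    labeled: list[PatientRecord] = []
    for rec in subpop:
        label = rec.gold_diagnosis
        if label is None:
            trace = diagnose(pm, rec, schema)
            label = trace.outcome
        if label is not None:
            labeled.append(PatientRecord(rec.patient_id, rec.values, label))
    if not labeled:
        graft = DecisionNode("g", "grafted", diagnosis=Diagnosis.NoHF)
    elif len(labeled) < 2 * params.min_samples_leaf:
        counts = {d: 0 for d in Diagnosis}
        for rec in labeled:
            counts[rec.gold_diagnosis] += 1
        graft = DecisionNode("g", "grafted", diagnosis=max(counts, key=lambda d: counts[d]))
    else:
        graft = induce_cart(labeled, params, schema).root
    _relabel_grafted(graft, counter)
    return graft


def _gap_intervals(node: DecisionNode, schema: AttributeSchema) -> list[Interval]:
    """Sub-intervals of the attribute's valid range no branch covers."""
    lo, hi = schema[node.attribute].valid_range
    ivs = sorted((b.interval for b in node.branches), key=lambda iv: (iv.lo, not iv.lo_closed))
    gaps: list[Interval] = []
    cur, cur_closed = lo, True  # next uncovered point is cur (inclusive if cur_closed)
    for iv in ivs:
        starts_before = iv.lo < cur or (iv.lo == cur and (iv.lo_closed or not cur_closed))
        if not starts_before:
            gaps.append(Interval(cur, iv.lo, cur_closed, not iv.lo_closed))
        if iv.hi > cur or (iv.hi == cur and iv.hi_closed):
            cur, cur_closed = iv.hi, not iv.hi_closed
    if cur < hi or (cur == hi and cur_closed):
        gaps.append(Interval(cur, math.inf, cur_closed, False))
    return gaps


def hybridize(ckm: DecisionTree, pm: DecisionTree, records: Sequence[PatientRecord],
              schema: Optional[AttributeSchema] = None,
              params: Optional[InductionParams] = None,
              tree_id: Optional[str] = None) -> DecisionTree:
    """Graft learned subtrees onto every coverage failure point of *ckm*.

    Returns the refined model (R-CKM).  Expert precedence: existing nodes,
    tests and leaves are copied unchanged, so CKM-covered records keep
    their diagnosis; grafts only add Not-Available branches and domain-gap
    branches, hence coverage over *records* is non-decreasing.
    """
    schema = schema or default_schema()
    params = (params or InductionParams()).validate()
    rckm = DecisionTree(tree_id or f"{ckm.tree_id}+{pm.tree_id}",
                        copy.deepcopy(ckm.root))
    by_id = {rec.patient_id: rec for rec in records}
    counter = [0]

    for _ in range(10):
        report = coverage(rckm, records, schema)
        if not report.uncovered:
            break
        nodes = {n.node_id: n for n in rckm.walk()}
        groups: dict[tuple[str, str], list[PatientRecord]] = {}
        for case in report.uncovered:
            groups.setdefault((case.node_id, case.reason), []).append(by_id[case.patient_id])
        progress = False
        for (node_id, reason), subpop in sorted(groups.items()):
            node = nodes[node_id]
            if reason == "missing":
                if node.na_child is not None or node.na_route is not None:
                    continue  # already routed; failure must be deeper next round
                node.na_child = _fit_graft(subpop, pm, schema, params, counter)
                progress = True
            else:  # domain gap
                if schema[node.attribute].is_binary:
                    have = {b.value for b in node.branches}
                    for missing_value in (False, True):
                        if missing_value not in have:
                            sub = [r for r in subpop if bool(r.get(node.attribute)) is missing_value]
                            node.branches.append(
                                Branch(_fit_graft(sub, pm, schema, params, counter),
                                       value=missing_value))
                            progress = True
                else:
                    for gap in _gap_intervals(node, schema):
                        sub = [r for r in subpop
                               if r.get(node.attribute) is not None
                               and gap.contains(float(r.get(node.attribute)))]
                        node.branches.append(
                            Branch(_fit_graft(sub, pm, schema, params, counter), interval=gap))
                        progress = True
                    node.branches.sort(
                        key=lambda b: (b.interval.lo, not b.interval.lo_closed))
        if not progress:
            break

    try:
        assert_valid(rckm, schema)
    except Exception as exc:
        raise HybridizationError(f"hybridization produced an invalid model: {exc}") from exc
    return rckm
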