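"""Decision-tree knowledge models: structure, JSON round-trip, validation,
and white-box execution with explanation traces.

A tree is a single-rooted, acyclic attribute-test tree.  Internal nodes
test one attribute: a continuous node carries an ordered list of interval
branches that must tile the attribute's valid range (no overlap, no gap);
a binary node carries exactly a false branch and a true branch.  A node
may additionally route Missing values, either to one of its ordinary
branches (``na_route``, the policy CART induction records) or down a
dedicated grafted subtree (``na_child``, what hybridization attaches).
Every node carries provenance: ``expert``, ``learned`` or ``grafted``.

Execution is fully inspectable: :func:`diagnose` returns a
:class:`DiagnosisTrace` listing, node by node, the attribute tested, the
value observed and the branch taken, and — when traversal dies at a
Missing value or a domain gap — the exact failure point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

from .errors import KnowledgeModelError
from .schema import AttributeSchema, Diagnosis, PatientRecord, default_schema

__all__ = [
    "Interval",
    "Branch",
    "DecisionNode",
    "DecisionTree",
    "TraceStep",
    "DiagnosisTrace",
    "TreeIssue",
    "validate_tree",
    "diagnose",
    "save_tree",
    "load_tree",
    "tree_to_dot",
]

PROVENANCES = ("expert", "learned", "grafted")


@dataclass(frozen=True)
class Interval:
    """A numeric interval with explicit bound closure; infinite bounds are
    always open."""

    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = False

    def __post_init__(self) -> None:
        if self.lo > self.hi or (self.lo == self.hi and not (self.lo_closed and self.hi_closed)):
            raise KnowledgeModelError(f"empty interval {self.describe('x')}")

    def contains(self, v: float) -> bool:
        above = v > self.lo or (self.lo_closed and v == self.lo)
        below = v < self.hi or (self.hi_closed and v == self.hi)
        return above and below

    def describe(self, attr: str) -> str:
        lo_inf, hi_inf = math.isinf(self.lo), math.isinf(self.hi)
        if lo_inf and hi_inf:
            return f"any {attr}"
        if lo_inf:
            return f"{attr} {'<=' if self.hi_closed else '<'} {self.hi:g}"
        if hi_inf:
            return f"{attr} {'>=' if self.lo_closed else '>'} {self.lo:g}"
        return (
            f"{self.lo:g} {'<=' if self.lo_closed else '<'} {attr} "
            f"{'<=' if self.hi_closed else '<'} {self.hi:g}"
        )


@dataclass
class Branch:
    """One outgoing edge of an internal node: an interval condition for
    continuous attributes, or a boolean value for binary ones."""

    child: "DecisionNode"
    interval: Optional[Interval] = None
    value: Optional[bool] = None

    def matches(self, v) -> bool:
        if self.interval is not None:
            return self.interval.contains(float(v))
        return bool(v) is self.value

    def describe(self, attr: str) -> str:
        if self.interval is not None:
            return self.interval.describe(attr)
        return f"{attr} is {'true' if self.value else 'false'}"


@dataclass
class DecisionNode:
    node_id: str
    provenance: str = "expert"
    # leaf payload
    diagnosis: Optional[Diagnosis] = None
    # internal payload
    attribute: Optional[str] = None
    branches: list[Branch] = field(default_factory=list)
    na_route: Optional[int] = None  # index into branches for Missing values
    na_child: Optional["DecisionNode"] = None  # dedicated Missing subtree

    @property
    def is_leaf(self) -> bool:
        return self.diagnosis is not None

    def walk(self) -> Iterator["DecisionNode"]:
        yield self
        for b in self.branches:
            yield from b.child.walk()
        if self.na_child is not None:
            yield from self.na_child.walk()


@dataclass
class DecisionTree:
    tree_id: str
    root: DecisionNode

    def walk(self) -> Iterator[DecisionNode]:
        return self.root.walk()

    def leaves(self) -> list[DecisionNode]:
        return [n for n in self.walk() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def provenance_counts(self) -> dict[str, int]:
        out = {p: 0 for p in PROVENANCES}
        for n in self.walk():
            out[n.provenance] += 1
        return out


# ---------------------------------------------------------------------------
# execution

@dataclass
class TraceStep:
    node_id: str
    attribute: str
    observed: object
    branch: str  # human-readable condition of the branch taken


@dataclass
class DiagnosisTrace:
    """Outcome of one tree traversal: a diagnosis with its full reasoning
    path, or an Uncovered verdict with the exact failure point."""

    outcome: Optional[Diagnosis]
    path: list[TraceStep]
    leaf_id: Optional[str] = None
    failure_node: Optional[str] = None
    failure_attribute: Optional[str] = None
    failure_reason: Optional[str] = None  # "missing" | "gap"

    @property
    def is_covered(self) -> bool:
        return self.outcome is not None


def diagnose(tree: DecisionTree, record: PatientRecord, schema: Optional[AttributeSchema] = None) -> DiagnosisTrace:
    """Deterministically traverse *tree* on *record*.

    Never raises on Missing values: a Missing value at a node with no NA
    routing (and likewise a value matching no branch) yields an Uncovered
    trace pointing at the failure node.
    """
    node = tree.root
    path: list[TraceStep] = []
    guard = 0
    while not node.is_leaf:
        guard += 1
        if guard > 10000:
            raise KnowledgeModelError(f"traversal of tree {tree.tree_id!r} did not terminate")
        value = record.get(node.attribute)
        if value is None:
            if node.na_child is not None:
                path.append(TraceStep(node.node_id, node.attribute, None, f"{node.attribute} is missing"))
                node = node.na_child
                continue
            if node.na_route is not None:
                b = node.branches[node.na_route]
                path.append(
                    TraceStep(node.node_id, node.attribute, None,
                              f"{node.attribute} is missing -> {b.describe(node.attribute)}")
                )
                node = b.child
                continue
            return DiagnosisTrace(None, path, failure_node=node.node_id,
                                  failure_attribute=node.attribute, failure_reason="missing")
        taken = next((b for b in node.branches if b.matches(value)), None)
        if taken is None:
            return DiagnosisTrace(None, path, failure_node=node.node_id,
                                  failure_attribute=node.attribute, failure_reason="gap")
        path.append(TraceStep(node.node_id, node.attribute, value, taken.describe(node.attribute)))
        node = taken.child
    return DiagnosisTrace(node.diagnosis, path, leaf_id=node.node_id)


# ---------------------------------------------------------------------------
# validation

@dataclass
class TreeIssue:
    severity: str  # "error" | "info"
    kind: str
    node_id: str
    message: str


def validate_tree(tree: DecisionTree, schema: Optional[AttributeSchema] = None) -> list[TreeIssue]:
    """Structural diagnostics: branch overlaps/gaps, duplicate ids, bad
    provenance, leafless nodes.  Nodes that cannot route Missing values are
    reported as informational NA-gap notes, not errors."""
    schema = schema or default_schema()
    issues: list[TreeIssue] = []
    seen_ids: set[str] = set()

    def err(kind: str, node: DecisionNode, msg: str) -> None:
        issues.append(TreeIssue("error", kind, node.node_id, msg))

    for node in tree.walk():
        if node.node_id in seen_ids:
            err("duplicate-id", node, f"node id {node.node_id!r} is not unique")
        seen_ids.add(node.node_id)
        if node.provenance not in PROVENANCES:
            err("provenance", node, f"unknown provenance {node.provenance!r}")
        if node.is_leaf:
            if node.branches or node.na_child is not None:
                err("leaf-branches", node, "leaf node must not have branches")
            continue
        if node.attribute is None or not node.branches:
            err("leafless", node, "internal node needs an attribute and branches")
            continue
        if node.attribute not in schema:
            err("unknown-attribute", node, f"attribute {node.attribute!r} not in schema")
            continue
        attr = schema[node.attribute]
        if node.na_route is not None and node.na_child is not None:
            err("na-conflict", node, "node has both na_route and na_child")
        if node.na_route is not None and not (0 <= node.na_route < len(node.branches)):
            err("na-route", node, f"na_route {node.na_route} out of range")
        if attr.is_binary:
            vals = sorted((b.value for b in node.branches if b.value is not None))
            if any(b.interval is not None for b in node.branches) or vals != [False, True]:
                err("binary-branches", node, "binary node needs exactly a false and a true branch")
        else:
            if any(b.interval is None for b in node.branches):
                err("interval-branches", node, "continuous node branches need intervals")
                continue
            lo, hi = attr.valid_range
            ivs = sorted((b.interval for b in node.branches), key=lambda iv: (iv.lo, not iv.lo_closed))
            if not ivs[0].contains(lo):
                err("gap", node, f"branches do not cover the range start {lo:g}")
            for a, b in zip(ivs, ivs[1:]):
                if a.hi < b.lo or (a.hi == b.lo and not a.hi_closed and not b.lo_closed):
                    err("gap", node, f"gap between {a.describe(node.attribute)} and {b.describe(node.attribute)}")
                elif a.hi > b.lo or (a.hi == b.lo and a.hi_closed and b.lo_closed):
                    err("overlap", node, f"{a.describe(node.attribute)} overlaps {b.describe(node.attribute)}")
            if not ivs[-1].contains(hi):
                err("gap", node, f"branches do not cover the range end {hi:g}")
        if node.na_route is None and node.na_child is None:
            issues.append(TreeIssue("info", "na-gap", node.node_id,
                                    f"Missing {node.attribute!r} is uncovered at this node"))
    return issues


def assert_valid(tree: DecisionTree, schema: Optional[AttributeSchema] = None) -> DecisionTree:
    problems = [i for i in validate_tree(tree, schema) if i.severity == "error"]
    if problems:
        detail = "; ".join(f"{i.node_id}: {i.message}" for i in problems[:5])
        raise KnowledgeModelError(f"tree {tree.tree_id!r} is invalid: {detail}")
    return tree


# ---------------------------------------------------------------------------
# JSON serialization

_FORMAT = "hfdx-tree"
_VERSION = 1


def _bound_to_json(x: float) -> Optional[float]:
    return None if math.isinf(x) else x


def _bound_from_json(x, sign: float) -> float:
    return sign * math.inf if x is None else float(x)


def _node_to_dict(node: DecisionNode) -> dict:
    d: dict = {"id": node.node_id, "provenance": node.provenance}
    if node.is_leaf:
        d["leaf"] = node.diagnosis.value
        return d
    d["attribute"] = node.attribute
    branches = []
    for b in node.branches:
        bd: dict = {"child": _node_to_dict(b.child)}
        if b.interval is not None:
            bd["range"] = [_bound_to_json(b.interval.lo), _bound_to_json(b.interval.hi)]
            bd["closed"] = [b.interval.lo_closed, b.interval.hi_closed]
        else:
            bd["value"] = b.value
        branches.append(bd)
    d["branches"] = branches
    if node.na_route is not None:
        d["na"] = {"route": node.na_route}
    elif node.na_child is not None:
        d["na"] = {"child": _node_to_dict(node.na_child)}
    return d


def _node_from_dict(d: dict) -> DecisionNode:
    try:
        node_id = d["id"]
        provenance = d.get("provenance", "expert")
        if "leaf" in d:
            return DecisionNode(node_id, provenance, diagnosis=Diagnosis(d["leaf"]))
        branches = []
        for bd in d["branches"]:
            child = _node_from_dict(bd["child"])
            if "range" in bd:
                lo = _bound_from_json(bd["range"][0], -1.0)
                hi = _bound_from_json(bd["range"][1], +1.0)
                closed = bd.get("closed", [True, False])
                branches.append(Branch(child, interval=Interval(lo, hi, closed[0], closed[1])))
            else:
                branches.append(Branch(child, value=bool(bd["value"])))
        na = d.get("na") or {}
        na_route = na.get("route")
        na_child = _node_from_dict(na["child"]) if "child" in na else None
        return DecisionNode(node_id, provenance, attribute=d["attribute"],
                            branches=branches, na_route=na_route, na_child=na_child)
    except (KeyError, ValueError, TypeError) as exc:
        raise KnowledgeModelError(f"malformed tree node document: {exc}") from exc


def tree_to_dict(tree: DecisionTree) -> dict:
    return {"format": _FORMAT, "version": _VERSION, "tree_id": tree.tree_id,
            "root": _node_to_dict(tree.root)}


def tree_from_dict(doc: dict, schema: Optional[AttributeSchema] = None) -> DecisionTree:
    if doc.get("format") != _FORMAT:
        raise KnowledgeModelError(f"not a {_FORMAT} document")
    tree = DecisionTree(doc.get("tree_id", "tree"), _node_from_dict(doc["root"]))
    return assert_valid(tree, schema)


def save_tree(tree: DecisionTree, path: Union[str, Path],
              schema: Optional[AttributeSchema] = None) -> None:
    """Write the tree as a JSON knowledge-model document (lossless)."""
    assert_valid(tree, schema)
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=2) + "\n")


def load_tree(path: Union[str, Path], schema: Optional[AttributeSchema] = None) -> DecisionTree:
    """Read and structurally validate a JSON knowledge-model document."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise KnowledgeModelError(f"malformed JSON in {path}: {exc}") from exc
    return tree_from_dict(doc, schema)


def tree_to_dot(tree: DecisionTree) -> str:
    """Render the tree as Graphviz DOT text (no graphviz dependency)."""
    lines = ["digraph tree {", "  node [shape=box];"]
    for node in tree.walk():
        if node.is_leaf:
            label = node.diagnosis.value
            shape = ', shape=ellipse'
        else:
            label = node.attribute
            shape = ""
        lines.append(f'  "{node.node_id}" [label="{label}\\n({node.provenance})"{shape}];')
        for b in node.branches:
            lines.append(f'  "{node.node_id}" -> "{b.child.node_id}" [label="{b.describe(node.attribute)}"];')
        if node.na_child is not None:
            lines.append(f'  "{node.node_id}" -> "{node.na_child.node_id}" [label="missing", style=dashed];')
        elif node.na_route is not None:
            target = node.branches[node.na_route].child.node_id
            lines.append(f'  "{node.node_id}" -> "{target}" [label="missing", style=dotted];')
    lines.append("}")
    return "\n".join(lines)
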