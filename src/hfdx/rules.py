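"""Production-rule extraction and the shareable rule-base format.

Every root-to-leaf path of a decision tree becomes one conjunctive
IF-THEN rule; the rule set extracted from a valid tree is mutually
exclusive, and on any record the tree covers, exactly one rule fires and
agrees with tree traversal.  Rule bases serialize to a JSON document in
the spirit of a Medical Logic Module: each rule block carries an
identifier, machine-readable condition terms, human-readable condition
text, the conclusion, provenance, and optional terminology codes — the
unit of knowledge shared between systems.  Full Arden Syntax slot
grammar and HL7 virtual-medical-record bindings are intentionally out of
scope; the ``code_map`` hook attaches terminology codes per attribute.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import KnowledgeModelError
from .schema import Diagnosis, PatientRecord
from .tree import Branch, DecisionNode, DecisionTree, Interval

__all__ = ["Term", "ProductionRule", "RuleBase", "extract_rules",
           "export_rule_base", "load_rule_base"]

_OPS = ("<", "<=", ">", ">=", "range", "is_true", "is_false", "is_missing")


@dataclass(frozen=True)
class Term:
    """One conjunct of a rule condition.

    ``or_missing`` marks terms on branches that also absorb Missing
    values (the induced trees' majority-side routing)."""

    attribute: str
    op: str
    value: object = None  # number, or (lo, hi, lo_closed, hi_closed) for "range"
    or_missing: bool = False
    code: Optional[str] = None

    def satisfied(self, v) -> bool:
        if v is None:
            return self.or_missing or self.op == "is_missing"
        if self.op == "is_missing":
            return False
        if self.op == "is_true":
            return bool(v) is True
        if self.op == "is_false":
            return bool(v) is False
        x = float(v)
        if self.op == "<":
            return x < self.value
        if self.op == "<=":
            return x <= self.value
        if self.op == ">":
            return x > self.value
        if self.op == ">=":
            return x >= self.value
        lo, hi, lc, hc = self.value
        lo = -math.inf if lo is None else lo
        hi = math.inf if hi is None else hi
        return (x > lo or (lc and x == lo)) and (x < hi or (hc and x == hi))

    @property
    def text(self) -> str:
        if self.op == "is_missing":
            base = f"{self.attribute} is missing"
        elif self.op in ("is_true", "is_false"):
            base = f"{self.attribute} is {self.op[3:]}"
        elif self.op == "range":
            lo, hi, lc, hc = self.value
            base = (f"{lo:g} {'<=' if lc else '<'} {self.attribute} "
                    f"{'<=' if hc else '<'} {hi:g}")
        else:
            base = f"{self.attribute} {self.op} {self.value:g}"
        if self.or_missing:
            base = f"({base} or {self.attribute} is missing)"
        return base


def _term_from_branch(branch: Branch, attribute: str, or_missing: bool,
                      code: Optional[str]) -> Term:
    if branch.interval is None:
        op = "is_true" if branch.value else "is_false"
        return Term(attribute, op, or_missing=or_missing, code=code)
    iv = branch.interval
    lo_inf, hi_inf = math.isinf(iv.lo), math.isinf(iv.hi)
    if lo_inf and not hi_inf:
        return Term(attribute, "<=" if iv.hi_closed else "<", iv.hi, or_missing, code)
    if hi_inf and not lo_inf:
        return Term(attribute, ">=" if iv.lo_closed else ">", iv.lo, or_missing, code)
    return Term(attribute, "range", (iv.lo, iv.hi, iv.lo_closed, iv.hi_closed),
                or_missing, code)


@dataclass
class ProductionRule:
    rule_id: str
    conditions: list[Term]
    conclusion: Diagnosis
    provenance: str = "expert"

    def matches(self, record: PatientRecord) -> bool:
        return all(t.satisfied(record.get(t.attribute)) for t in self.conditions)

    @property
    def text(self) -> str:
        cond = " AND ".join(t.text for t in self.conditions) or "TRUE"
        return f"IF {cond} THEN {self.conclusion.value}"


@dataclass
class RuleBase:
    rules: list[ProductionRule]
    source_tree_id: str = ""
    code_map: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def apply(self, record: PatientRecord) -> tuple[Optional[Diagnosis], Optional[ProductionRule]]:
        """Fire the unique matching rule; (None, None) when no rule covers
        the record.  More than one match signals a corrupt rule base."""
        hits = [r for r in self.rules if r.matches(record)]
        if len(hits) > 1:
            ids = [r.rule_id for r in hits]
            raise KnowledgeModelError(f"rules {ids} are not mutually exclusive")
        if not hits:
            return None, None
        return hits[0].conclusion, hits[0]


def _rule_provenance(provs: Sequence[str]) -> str:
    if "grafted" in provs:
        return "grafted"
    if "learned" in provs:
        return "learned"
    return "expert"


def extract_rules(tree: DecisionTree, code_map: Optional[dict[str, str]] = None) -> RuleBase:
    """One rule per root-to-leaf path, conditions in root-to-leaf order.

    Traversals through a dedicated Not-Available subtree emit an
    ``attribute is missing`` term; branches that absorb Missing values by
    routing carry ``or_missing`` on their term.
    """
    code_map = code_map or {}
    rules: list[ProductionRule] = []

    def walk(node: DecisionNode, terms: list[Term], provs: list[str]) -> None:
        provs = provs + [node.provenance]
        if node.is_leaf:
            rules.append(ProductionRule(f"R{len(rules) + 1:03d}", list(terms),
                                        node.diagnosis, _rule_provenance(provs)))
            return
        code = code_map.get(node.attribute)
        for i, b in enumerate(node.branches):
            term = _term_from_branch(b, node.attribute, or_missing=(node.na_route == i), code=code)
            walk(b.child, terms + [term], provs)
        if node.na_child is not None:
            walk(node.na_child, terms + [Term(node.attribute, "is_missing", code=code)], provs)

    walk(tree.root, [], [])
    return RuleBase(rules, source_tree_id=tree.tree_id, code_map=dict(code_map))


# ---------------------------------------------------------------------------
# JSON rule-base documents

_FORMAT = "hfdx-rules"
_VERSION = 1


def _term_to_dict(t: Term) -> dict:
    d: dict = {"attribute": t.attribute, "op": t.op, "text": t.text}
    if t.op == "range":
        lo, hi, lc, hc = t.value
        d["value"] = [None if math.isinf(lo) else lo, None if math.isinf(hi) else hi, lc, hc]
    elif t.value is not None:
        d["value"] = t.value
    if t.or_missing:
        d["or_missing"] = True
    if t.code:
        d["code"] = t.code
    return d


def _term_from_dict(d: dict) -> Term:
    op = d["op"]
    if op not in _OPS:
        raise KnowledgeModelError(f"unknown condition operator {op!r}")
    value = d.get("value")
    if op == "range":
        lo, hi, lc, hc = value
        value = (-math.inf if lo is None else lo, math.inf if hi is None else hi, lc, hc)
    return Term(d["attribute"], op, value, d.get("or_missing", False), d.get("code"))


def export_rule_base(rb: RuleBase, path: Union[str, Path]) -> None:
    """Write the rule base as a shareable JSON document (lossless)."""
    doc = {
        "format": _FORMAT,
        "version": _VERSION,
        "source_tree_id": rb.source_tree_id,
        "code_map": rb.code_map,
        "rules": [
            {"id": r.rule_id, "provenance": r.provenance, "conclusion": r.conclusion.value,
             "conditions": [_term_to_dict(t) for t in r.conditions], "text": r.text}
            for r in rb.rules
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_rule_base(path: Union[str, Path]) -> RuleBase:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise KnowledgeModelError(f"malformed JSON in {path}: {exc}") from exc
    if doc.get("format") != _FORMAT:
        raise KnowledgeModelError(f"not a {_FORMAT} document")
    try:
        rules = [
            ProductionRule(r["id"], [_term_from_dict(t) for t in r["conditions"]],
                           Diagnosis(r["conclusion"]), r.get("provenance", "expert"))
            for r in doc["rules"]
        ]
    except (KeyError, ValueError, TypeError) as exc:
        raise KnowledgeModelError(f"malformed rule document: {exc}") from exc
    return RuleBase(rules, doc.get("source_tree_id", ""), doc.get("code_map", {}) or {})
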