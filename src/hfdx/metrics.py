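"""Diagnostic-accuracy metrics and cohort summaries.

Concordance is percent agreement with the gold-standard (specialist)
diagnosis.  Per-class concordance is within-gold-class agreement
(recall).  Sensitivity and specificity are computed on the binary
HF-vs-NoHF collapse of the four labels, and the association statistic is
the product-moment correlation (phi) of the binary gold/predicted codes.

Uncovered predictions — records the knowledge model reached no leaf for —
are excluded from the metrics by default and counted separately
(``uncovered="exclude"``); pass ``uncovered="discordant"`` to score them
as disagreements instead.  Cross-engine comparisons default to the
discordant convention so every engine is scored over the same
denominator regardless of its coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError
from .rules import RuleBase
from .schema import AttributeSchema, Diagnosis, PatientRecord, default_schema
from .tree import DecisionTree, diagnose

__all__ = [
    "EvaluationReport",
    "evaluate",
    "predict",
    "compare_engines",
    "subgroup_eval",
    "summarize_cohort",
    "ECHO_SET_B_KEEP",
]

_LABELS = list(Diagnosis)

#: Echo attributes retained by restricted echo "set B"; the full echo
#: panel defines set A.
ECHO_ATTRIBUTES = ("lvef", "lavi", "lvmi", "e_over_eprime", "septal_eprime", "trv", "gls")
ECHO_SET_B_KEEP = ("lvef", "lavi", "lvmi")

Engine = Union[DecisionTree, RuleBase]


@dataclass
class EvaluationReport:
    """Confusion matrix (gold x predicted, label order HFrEF, HFmrEF,
    HFpEF, NoHF) and the derived agreement metrics."""

    confusion: np.ndarray
    n: int
    n_uncovered: int
    uncovered_policy: str
    overall_concordance: float  # percent
    per_class_concordance: dict[Diagnosis, Optional[float]]
    sensitivity: Optional[float]
    specificity: Optional[float]
    association: Optional[float]
    degenerate_association: bool = False

    def confusion_frame(self) -> pd.DataFrame:
        names = [d.value for d in _LABELS]
        return pd.DataFrame(self.confusion, index=names, columns=names)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_uncovered": self.n_uncovered,
            "uncovered_policy": self.uncovered_policy,
            "overall_concordance": self.overall_concordance,
            "per_class_concordance": {d.value: v for d, v in self.per_class_concordance.items()},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "association": self.association,
            "confusion": self.confusion.tolist(),
        }


def evaluate(gold: Sequence[Diagnosis],
             predicted: Sequence[Optional[Diagnosis]],
             uncovered: str = "exclude") -> EvaluationReport:
    """Score predictions against the gold standard.

    ``predicted`` entries of None are Uncovered.  With the default
    ``exclude`` policy they drop out of every metric; with ``discordant``
    they keep their gold label in the denominators and count as
    disagreements (an uncovered HF patient is a false negative, an
    uncovered NoHF patient a false positive).
    """
    if len(gold) != len(predicted):
        raise EvaluationError(f"length mismatch: {len(gold)} gold vs {len(predicted)} predicted")
    if uncovered not in ("exclude", "discordant"):
        raise EvaluationError(f"unknown uncovered policy {uncovered!r}")
    pairs = list(zip(gold, predicted))
    covered = [(g, p) for g, p in pairs if p is not None]
    n_uncovered = len(pairs) - len(covered)
    if not covered and uncovered == "exclude":
        raise EvaluationError("no covered (gold, predicted) pairs to evaluate")

    conf = np.zeros((4, 4), dtype=int)
    for g, p in covered:
        conf[_LABELS.index(g), _LABELS.index(p)] += 1

    if uncovered == "exclude":
        denom_total = len(covered)
        class_denom = {d: int(conf[_LABELS.index(d)].sum()) for d in _LABELS}
        scored = covered
    else:
        denom_total = len(pairs)
        class_denom = {d: sum(1 for g, _ in pairs if g is d) for d in _LABELS}
        scored = pairs

    agree = int(np.trace(conf))
    overall = 100.0 * agree / denom_total
    per_class = {
        d: (100.0 * conf[_LABELS.index(d), _LABELS.index(d)] / class_denom[d]
            if class_denom[d] else None)
        for d in _LABELS
    }

    # binary HF-vs-NoHF collapse; under the discordant policy an
    # uncovered prediction counts against whichever side the gold was on
    tp = sum(1 for g, p in scored if g.is_hf and p is not None and p.is_hf)
    fn = sum(1 for g, p in scored if g.is_hf and (p is None or not p.is_hf))
    tn = sum(1 for g, p in scored if not g.is_hf and p is not None and not p.is_hf)
    fp = sum(1 for g, p in scored if not g.is_hf and (p is None or p.is_hf))
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None

    g_bin = np.array([1.0 if g.is_hf else 0.0 for g, p in covered])
    p_bin = np.array([1.0 if p.is_hf else 0.0 for g, p in covered])
    degenerate = len(covered) == 0 or bool(g_bin.std() == 0 or p_bin.std() == 0)
    assoc = None if degenerate else float(np.corrcoef(g_bin, p_bin)[0, 1])

    return EvaluationReport(conf, denom_total, n_uncovered, uncovered, overall,
                            per_class, sens, spec, assoc, degenerate)


def predict(engine: Engine, records: Sequence[PatientRecord],
            schema: Optional[AttributeSchema] = None) -> list[Optional[Diagnosis]]:
    """Run a knowledge model (tree or rule base) over records; None marks
    an Uncovered record."""
    schema = schema or default_schema()
    out: list[Optional[Diagnosis]] = []
    for rec in records:
        if isinstance(engine, RuleBase):
            dx, _ = engine.apply(rec)
        else:
            dx = diagnose(engine, rec, schema).outcome
        out.append(dx)
    return out


@dataclass
class ComparisonReport:
    reports: dict[str, EvaluationReport]
    flagged: list[str] = field(default_factory=list)  # engines uncovered on > 50%

    def table(self) -> pd.DataFrame:
        rows = {}
        for name, rep in self.reports.items():
            row = {"overall": rep.overall_concordance}
            row.update({d.value: rep.per_class_concordance[d] for d in _LABELS})
            row.update({"sensitivity": rep.sensitivity, "specificity": rep.specificity,
                        "n_uncovered": rep.n_uncovered})
            rows[name] = row
        return pd.DataFrame(rows).T

    def to_dict(self) -> dict:
        return {"engines": {k: v.to_dict() for k, v in self.reports.items()},
                "flagged": self.flagged}


def compare_engines(records: Sequence[PatientRecord], engines: dict[str, Engine],
                    schema: Optional[AttributeSchema] = None,
                    uncovered: str = "discordant") -> ComparisonReport:
    """Evaluate several engines on the identical cohort.

    Engines failing to cover more than half the records are flagged (not
    fatal).  The default discordant policy keeps denominators comparable
    across engines of different coverage.
    """
    if not engines:
        raise EvaluationError("compare_engines needs at least one engine")
    schema = schema or default_schema()
    gold = [r.gold_diagnosis for r in records]
    if any(g is None for g in gold):
        raise EvaluationError("all records need a gold diagnosis for comparison")
    reports, flagged = {}, []
    for name, engine in engines.items():
        preds = predict(engine, records, schema)
        reports[name] = evaluate(gold, preds, uncovered=uncovered)
        if reports[name].n_uncovered > len(records) / 2:
            flagged.append(name)
    return ComparisonReport(reports, flagged)


def subgroup_eval(records: Sequence[PatientRecord], engine: Engine,
                  subset: Union[str, tuple[str, Sequence[float]]] = "setA",
                  schema: Optional[AttributeSchema] = None,
                  uncovered: str = "exclude"):
    """Echo-subset or age-stratified evaluation.

    ``"setA"`` evaluates on the records as given (full echo panel);
    ``"setB"`` first masks every echo attribute except LVEF, LAVI and
    LVMI to Missing.  ``("age", [lo, m1, ..., hi])`` partitions records
    into [lo, m1), [m1, m2), ... [m_k, hi] age strata and returns one
    report per stratum (strata with no records report n=0 and no
    metrics).
    """
    schema = schema or default_schema()
    gold = [r.gold_diagnosis for r in records]
    if subset == "setA":
        return evaluate(gold, predict(engine, records, schema), uncovered=uncovered)
    if subset == "setB":
        masked = [r.masked([a for a in ECHO_ATTRIBUTES if a not in ECHO_SET_B_KEEP])
                  for r in records]
        return evaluate(gold, predict(engine, masked, schema), uncovered=uncovered)
    kind, bounds = subset
    if kind != "age" or len(bounds) < 2 or sorted(bounds) != list(bounds):
        raise EvaluationError(f"invalid subset {subset!r}")
    out = {}
    for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        last = i == len(bounds) - 2
        stratum = [r for r in records
                   if r.get("age") is not None
                   and lo <= r.get("age") and (r.get("age") <= hi if last else r.get("age") < hi)]
        label = f"[{lo:g}, {hi:g}{']' if last else ')'}"
        if not stratum:
            out[label] = None
            continue
        out[label] = evaluate([r.gold_diagnosis for r in stratum],
                              predict(engine, stratum, schema), uncovered=uncovered)
    return out


def summarize_cohort(records: Sequence[PatientRecord],
                     schema: Optional[AttributeSchema] = None) -> pd.DataFrame:
    """Group summary (HF vs NoHF) in the style of a baseline-characteristics
    table: mean +/- SD and Student's t-test for continuous attributes,
    percent and a chi-square test for binary ones — falling back to
    Fisher's exact test when any expected cell count of the 2x2 table is
    below 5.  Degenerate comparisons (no variance) report P = 1.0 with a
    flag.
    """
    schema = schema or default_schema()
    hf = [r for r in records if r.gold_diagnosis is not None and r.gold_diagnosis.is_hf]
    no = [r for r in records if r.gold_diagnosis is Diagnosis.NoHF]
    if not hf or not no:
        raise EvaluationError("summary needs both an HF and a NoHF group")
    rows = []
    for attr in schema:
        a = [r.get(attr.name) for r in no]
        b = [r.get(attr.name) for r in hf]
        a = [x for x in a if x is not None]
        b = [x for x in b if x is not None]
        row = {"attribute": attr.name, "kind": attr.kind, "units": attr.units,
               "n_no_hf": len(a), "n_hf": len(b), "test": "", "p_value": np.nan,
               "degenerate": False}
        if not a or not b:
            rows.append(row)
            continue
        if attr.is_binary:
            k = np.array([[sum(a), len(a) - sum(a)], [sum(b), len(b) - sum(b)]], dtype=float)
            row["no_hf"] = f"{100.0 * sum(a) / len(a):.1f}%"
            row["hf"] = f"{100.0 * sum(b) / len(b):.1f}%"
            expected = np.outer(k.sum(1), k.sum(0)) / k.sum()
            if (expected < 5).any():
                row["test"] = "fisher"
                row["p_value"] = float(stats.fisher_exact(k)[1])
            else:
                row["test"] = "chi2"
                row["p_value"] = float(stats.chi2_contingency(k, correction=False)[1])
        else:
            av, bv = np.array(a, float), np.array(b, float)
            row["no_hf"] = f"{av.mean():.1f} ± {av.std(ddof=1) if len(av) > 1 else 0:.1f}"
            row["hf"] = f"{bv.mean():.1f} ± {bv.std(ddof=1) if len(bv) > 1 else 0:.1f}"
            row["test"] = "t"
            if (len(av) > 1 and av.std(ddof=1) > 0) or (len(bv) > 1 and bv.std(ddof=1) > 0):
                row["p_value"] = float(stats.ttest_ind(av, bv, equal_var=True)[1])
            else:
                row["p_value"], row["degenerate"] = 1.0, True
        rows.append(row)
    return pd.DataFrame(rows).set_index("attribute")
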