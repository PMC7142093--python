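"""Expert-driven clinical knowledge model (CKM) for heart-failure diagnosis.

The guideline logic encoded here: a patient has heart failure only if they
show HF symptoms or signs AND meet an objective criterion — reduced
systolic function or supporting structural/functional evidence.  Patients
with HF are phenotyped by ejection fraction: HFrEF (LVEF < 40%), HFmrEF
(40% <= LVEF < 50%), HFpEF (LVEF >= 50%).  For the non-reduced phenotypes
the model requires at least one piece of supporting evidence: elevated
NT-proBNP, left-atrial enlargement (LAVI), ventricular hypertrophy (LVMI,
sex-specific), elevated filling pressure (E/e'), or an abnormal ECG.

The default CKM deliberately has no Missing-value routing: a record with a
Missing value on its path is Uncovered.  Supplying those Not-Available
paths is the job of the hybridization step.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import ConfigError, NAClassificationError
from .schema import Diagnosis
from .tree import Branch, DecisionNode, DecisionTree, Interval

__all__ = ["LVEFClass", "classify_lvef", "ThresholdConfig", "default_hf_ckm"]

INF = float("inf")


class LVEFClass(Enum):
    REDUCED = "reduced"
    MID_RANGE = "mid_range"
    PRESERVED = "preserved"


def classify_lvef(lvef: float, reduced_below: float = 40.0, preserved_from: float = 50.0) -> LVEFClass:
    """Phenotype an ejection fraction (percent).

    Boundaries are half-open exactly as the guideline states them:
    [0, 40) reduced, [40, 50) mid-range, [50, 100] preserved.
    """
    if lvef is None:
        raise NAClassificationError("LVEF is Missing; use a knowledge model with NA routing")
    lvef = float(lvef)
    if not (0.0 <= lvef <= 100.0):
        raise ValueError(f"LVEF {lvef} outside [0, 100]")
    if lvef < reduced_below:
        return LVEFClass.REDUCED
    if lvef < preserved_from:
        return LVEFClass.MID_RANGE
    return LVEFClass.PRESERVED


@dataclass(frozen=True)
class ThresholdConfig:
    """Tunable thresholds of the expert model.

    The supporting-evidence defaults follow the 2016 European guideline
    style: NT-proBNP >= 125 pg/L, LAVI > 34 mL/m2, LVMI >= 115 (men) /
    95 (women) mg/m2, E/e' >= 13.  LVEF phenotype cut-offs are fixed by
    definition but configurable for sensitivity analyses.
    """

    lvef_reduced_below: float = 40.0
    lvef_preserved_from: float = 50.0
    nt_probnp_min: float = 125.0
    lavi_above: float = 34.0
    lvmi_min_male: float = 115.0
    lvmi_min_female: float = 95.0
    e_over_eprime_min: float = 13.0

    def validate(self) -> "ThresholdConfig":
        for name in ("lvef_reduced_below", "lvef_preserved_from", "nt_probnp_min",
                     "lavi_above", "lvmi_min_male", "lvmi_min_female", "e_over_eprime_min"):
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigError(f"threshold {name} must be positive, got {v}")
        if not (self.lvef_reduced_below < self.lvef_preserved_from):
            raise ConfigError("LVEF reduced cut-off must lie below the preserved cut-off")
        return self


def _leaf(node_id: str, dx: Diagnosis) -> DecisionNode:
    return DecisionNode(node_id, "expert", diagnosis=dx)


def _support_chain(prefix: str, outcome: Diagnosis, cfg: ThresholdConfig) -> DecisionNode:
    """Supporting-evidence subtree: any one positive criterion confirms
    *outcome*; all negative ends in NoHF.  Checked in the order NT-proBNP,
    LAVI, LVMI (via sex), E/e', abnormal ECG."""

    def cont(node_id: str, attr: str, lo_interval: Interval, hi_interval: Interval,
             below: DecisionNode, above: DecisionNode) -> DecisionNode:
        return DecisionNode(node_id, "expert", attribute=attr,
                            branches=[Branch(below, interval=lo_interval),
                                      Branch(above, interval=hi_interval)])

    ecg = DecisionNode(f"{prefix}_ecg", "expert", attribute="abnormal_ecg",
                       branches=[Branch(_leaf(f"{prefix}_ecg_no", Diagnosis.NoHF), value=False),
                                 Branch(_leaf(f"{prefix}_ecg_yes", outcome), value=True)])
    ee = cont(f"{prefix}_ee", "e_over_eprime",
              Interval(-INF, cfg.e_over_eprime_min, False, False),
              Interval(cfg.e_over_eprime_min, INF, True, False),
              ecg, _leaf(f"{prefix}_ee_yes", outcome))

    def lvmi_node(node_id: str, cut: float) -> DecisionNode:
        return cont(node_id, "lvmi",
                    Interval(-INF, cut, False, False),
                    Interval(cut, INF, True, False),
                    ee, _leaf(f"{node_id}_yes", outcome))

    # E/e' and downstream nodes appear once per sex arm so every node id
    # stays unique in the serialized document.
    ecg_f = DecisionNode(f"{prefix}_ecg_f", "expert", attribute="abnormal_ecg",
                         branches=[Branch(_leaf(f"{prefix}_ecg_f_no", Diagnosis.NoHF), value=False),
                                   Branch(_leaf(f"{prefix}_ecg_f_yes", outcome), value=True)])
    ee_f = cont(f"{prefix}_ee_f", "e_over_eprime",
                Interval(-INF, cfg.e_over_eprime_min, False, False),
                Interval(cfg.e_over_eprime_min, INF, True, False),
                ecg_f, _leaf(f"{prefix}_ee_f_yes", outcome))
    lvmi_f = cont(f"{prefix}_lvmi_f", "lvmi",
                  Interval(-INF, cfg.lvmi_min_female, False, False),
                  Interval(cfg.lvmi_min_female, INF, True, False),
                  ee_f, _leaf(f"{prefix}_lvmi_f_yes", outcome))
    lvmi_m = lvmi_node(f"{prefix}_lvmi_m", cfg.lvmi_min_male)
    sex = DecisionNode(f"{prefix}_sex", "expert", attribute="male",
                       branches=[Branch(lvmi_f, value=False), Branch(lvmi_m, value=True)])
    lavi = cont(f"{prefix}_lavi", "lavi",
                Interval(-INF, cfg.lavi_above, False, True),   # lavi <= cut
                Interval(cfg.lavi_above, INF, False, False),   # lavi >  cut
                sex, _leaf(f"{prefix}_lavi_yes", outcome))
    bnp = cont(f"{prefix}_bnp", "nt_probnp",
               Interval(-INF, cfg.nt_probnp_min, False, False),
               Interval(cfg.nt_probnp_min, INF, True, False),
               lavi, _leaf(f"{prefix}_bnp_yes", outcome))
    return bnp


def default_hf_ckm(config: Optional[ThresholdConfig] = None) -> DecisionTree:
    """Build the default expert clinical knowledge model.

    Root: HF symptoms/signs (absent -> NoHF).  Then the LVEF phenotype
    node; reduced LVEF alone establishes HFrEF, while the mid-range and
    preserved phenotypes additionally require supporting evidence and
    otherwise resolve to NoHF.  All provenance is ``expert`` and no node
    routes Missing values.
    """
    cfg = (config or ThresholdConfig()).validate()
    mr = _support_chain("mr", Diagnosis.HFmrEF, cfg)
    pe = _support_chain("pe", Diagnosis.HFpEF, cfg)
    lvef = DecisionNode(
        "lvef", "expert", attribute="lvef",
        branches=[
            Branch(_leaf("lvef_reduced", Diagnosis.HFrEF),
                   interval=Interval(-INF, cfg.lvef_reduced_below, False, False)),
            Branch(mr, interval=Interval(cfg.lvef_reduced_below, cfg.lvef_preserved_from, True, False)),
            Branch(pe, interval=Interval(cfg.lvef_preserved_from, INF, True, False)),
        ],
    )
    root = DecisionNode("symptoms", "expert", attribute="hf_symptoms_signs",
                        branches=[Branch(_leaf("no_symptoms", Diagnosis.NoHF), value=False),
                                  Branch(lvef, value=True)])
    return DecisionTree("ckm-default", root)
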