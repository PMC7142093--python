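"""Seeded synthetic patient-cohort generator.

Emulates the marginal per-class distributions of a retrospective
heart-failure test cohort (n = 598: 108 NoHF, 199 HFrEF, 63 HFmrEF,
228 HFpEF): each continuous attribute is drawn from a truncated normal
(or, for the heavily right-skewed NT-proBNP, a lognormal matched to the
printed mean/SD), each binary attribute from a Bernoulli with the
printed prevalence.  Attributes are sampled independently within class —
only marginals are published, so no correlation structure is imposed.
LVEF is truncated to the class's phenotype interval ([5, 40) HFrEF,
[40, 50) HFmrEF, [50, 85] HFpEF and, by a documented modeling choice,
NoHF), so generated gold labels are consistent with the ejection-fraction
subtype definitions.  Missingness is injected per attribute,
independently and seeded, after sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import CohortSpecError, SchemaError
from .schema import AttributeSchema, Diagnosis, PatientRecord, default_schema

__all__ = [
    "ContinuousParams",
    "ClassSpec",
    "CohortSpec",
    "table1_default_spec",
    "generate_cohort",
    "inject_missingness",
    "truncated_mean",
]


@dataclass(frozen=True)
class ContinuousParams:
    """Generative parameters of one continuous attribute in one class.

    ``mean``/``sd`` are the target (untruncated) moments; ``lo``/``hi``
    the truncation interval, ``hi_open`` marking a strict upper bound
    (used for the LVEF phenotype intervals).  ``family`` is ``normal`` or
    ``lognormal`` (mean/SD matched on the natural scale).
    """

    mean: float
    sd: float
    lo: float
    hi: float
    hi_open: bool = False
    family: str = "normal"
    decimals: int = 1

    def validate(self, name: str = "") -> "ContinuousParams":
        if self.sd <= 0:
            raise CohortSpecError(f"{name}: sd must be positive")
        if not (self.lo < self.hi):
            raise CohortSpecError(f"{name}: empty truncation interval [{self.lo}, {self.hi}]")
        if self.family not in ("normal", "lognormal"):
            raise CohortSpecError(f"{name}: unknown family {self.family!r}")
        if self.family == "lognormal" and (self.mean <= 0 or self.lo < 0):
            raise CohortSpecError(f"{name}: lognormal needs positive support")
        return self

    def _log_params(self) -> tuple[float, float]:
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            a = (self.lo - self.mean) / self.sd
            b = (self.hi - self.mean) / self.sd
            x = stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                    size=size, random_state=rng)
        else:
            mu, sigma = self._log_params()
            a = -np.inf if self.lo <= 0 else (math.log(self.lo) - mu) / sigma
            b = (math.log(self.hi) - mu) / sigma
            x = np.exp(stats.truncnorm.rvs(a, b, loc=mu, scale=sigma,
                                           size=size, random_state=rng))
        x = np.round(x, self.decimals)
        step = 10.0 ** -self.decimals
        top = self.hi - step if self.hi_open else self.hi
        return np.clip(x, self.lo, top)


def truncated_mean(p: ContinuousParams) -> float:
    """Analytic expectation of the truncated distribution (the oracle the
    generator's sample means are tested against)."""
    if p.family == "normal":
        a = (p.lo - p.mean) / p.sd
        b = (p.hi - p.mean) / p.sd
        return float(stats.truncnorm.mean(a, b, loc=p.mean, scale=p.sd))
    mu, sigma = p._log_params()
    a = -math.inf if p.lo <= 0 else (math.log(p.lo) - mu) / sigma
    b = (math.log(p.hi) - mu) / sigma
    phi = stats.norm.cdf
    denom = phi(b) - phi(a)
    return float(math.exp(mu + sigma ** 2 / 2) * (phi(b - sigma) - phi(a - sigma)) / denom)


@dataclass(frozen=True)
class ClassSpec:
    continuous: dict[str, ContinuousParams]
    binary: dict[str, float]  # attribute -> prevalence


@dataclass
class CohortSpec:
    class_priors: dict[Diagnosis, float]
    classes: dict[Diagnosis, ClassSpec]
    n: int = 598
    seed: int = 0
    missingness: dict[str, float] = field(default_factory=dict)

    def validate(self, schema: Optional[AttributeSchema] = None) -> "CohortSpec":
        schema = schema or default_schema()
        if self.n < 0:
            raise CohortSpecError("cohort size must be non-negative")
        total = sum(self.class_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise CohortSpecError(f"class priors must sum to 1 (got {total})")
        if any(p < 0 for p in self.class_priors.values()):
            raise CohortSpecError("class priors must be non-negative")
        for dx, cls in self.classes.items():
            for name, p in cls.continuous.items():
                attr = schema[name]
                p.validate(f"{dx.value}.{name}")
                lo, hi = attr.valid_range
                if p.lo < lo or p.hi > hi:
                    raise CohortSpecError(
                        f"{dx.value}.{name}: truncation [{p.lo}, {p.hi}] outside valid range")
            for name, prev in cls.binary.items():
                if not schema[name].is_binary:
                    raise CohortSpecError(f"{dx.value}.{name}: not a binary attribute")
                if not (0.0 <= prev <= 1.0):
                    raise CohortSpecError(f"{dx.value}.{name}: prevalence {prev} outside [0, 1]")
        for name, rate in self.missingness.items():
            if name not in schema:
                raise SchemaError(f"missingness rate for unknown attribute {name!r}")
            if not (0.0 <= rate <= 1.0):
                raise CohortSpecError(f"missingness rate {rate} for {name!r} outside [0, 1]")
        return self

    def with_missingness(self, rate: float,
                         schema: Optional[AttributeSchema] = None) -> "CohortSpec":
        """A copy applying one MCAR rate to every attribute."""
        schema = schema or default_schema()
        return CohortSpec(dict(self.class_priors), dict(self.classes), self.n, self.seed,
                          {name: rate for name in schema.names})


# Per-class generative parameters: mean, SD and prevalence per attribute,
# class order NoHF / HFrEF / HFmrEF / HFpEF.
_CONTINUOUS: dict[str, dict[str, tuple]] = {
    # attr: {family, decimals?}, per-class (mean, sd, lo, hi, hi_open)
    "age": {
        Diagnosis.NoHF: (64.8, 13.8), Diagnosis.HFrEF: (70.3, 14.6),
        Diagnosis.HFmrEF: (74.7, 14.1), Diagnosis.HFpEF: (75.2, 10.6),
    },
    "nt_probnp": {
        Diagnosis.NoHF: (82.4, 68.0), Diagnosis.HFrEF: (15665.0, 12604.0),
        Diagnosis.HFmrEF: (8634.0, 9666.0), Diagnosis.HFpEF: (5595.0, 9306.0),
    },
    "lvef": {
        Diagnosis.NoHF: (64.1, 6.5), Diagnosis.HFrEF: (27.1, 7.5),
        Diagnosis.HFmrEF: (45.3, 2.6), Diagnosis.HFpEF: (61.6, 6.5),
    },
    "lavi": {
        Diagnosis.NoHF: (31.2, 8.5), Diagnosis.HFrEF: (60.5, 18.6),
        Diagnosis.HFmrEF: (52.6, 27.5), Diagnosis.HFpEF: (48.0, 19.4),
    },
    "lvmi": {
        Diagnosis.NoHF: (83.4, 18.3), Diagnosis.HFrEF: (151.0, 41.5),
        Diagnosis.HFmrEF: (129.0, 50.7), Diagnosis.HFpEF: (106.0, 33.9),
    },
    "e_over_eprime": {
        Diagnosis.NoHF: (9.8, 3.5), Diagnosis.HFrEF: (22.9, 10.34),
        Diagnosis.HFmrEF: (17.4, 8.6), Diagnosis.HFpEF: (15.6, 8.3),
    },
    "septal_eprime": {
        Diagnosis.NoHF: (6.9, 2.4), Diagnosis.HFrEF: (4.2, 1.7),
        Diagnosis.HFmrEF: (5.1, 2.3), Diagnosis.HFpEF: (5.6, 2.2),
    },
    "trv": {
        Diagnosis.NoHF: (2.6, 1.5), Diagnosis.HFrEF: (3.0, 0.7),
        Diagnosis.HFmrEF: (2.8, 0.5), Diagnosis.HFpEF: (2.8, 0.7),
    },
    "gls": {
        Diagnosis.NoHF: (16.4, 3.9), Diagnosis.HFrEF: (7.1, 2.7),
        Diagnosis.HFmrEF: (10.4, 2.8), Diagnosis.HFpEF: (14.6, 4.3),
    },
}

_BINARY: dict[str, dict[Diagnosis, float]] = {
    "male": {Diagnosis.NoHF: 0.37, Diagnosis.HFrEF: 0.543,
             Diagnosis.HFmrEF: 0.524, Diagnosis.HFpEF: 0.50},
    "hf_symptoms_signs": {Diagnosis.NoHF: 0.815, Diagnosis.HFrEF: 0.94,
                          Diagnosis.HFmrEF: 0.841, Diagnosis.HFpEF: 0.877},
    "clinical_history": {Diagnosis.NoHF: 0.148, Diagnosis.HFrEF: 0.663,
                         Diagnosis.HFmrEF: 0.556, Diagnosis.HFpEF: 0.377},
    "physical_exam": {Diagnosis.NoHF: 0.093, Diagnosis.HFrEF: 0.608,
                      Diagnosis.HFmrEF: 0.492, Diagnosis.HFpEF: 0.439},
    "abnormal_ecg": {Diagnosis.NoHF: 0.46, Diagnosis.HFrEF: 0.995,
                     Diagnosis.HFmrEF: 0.968, Diagnosis.HFpEF: 0.862},
}

# Truncation intervals; LVEF enforces the phenotype definition per class
# (NoHF restricted to preserved systolic function — a modeling choice
# keeping the generative classes separable in principle).
_LVEF_TRUNC = {
    Diagnosis.NoHF: (50.0, 85.0, False),
    Diagnosis.HFrEF: (5.0, 40.0, True),
    Diagnosis.HFmrEF: (40.0, 50.0, True),
    Diagnosis.HFpEF: (50.0, 85.0, False),
}
_TRUNC_DEFAULT = {
    "age": (18.0, 100.0),
    "nt_probnp": (0.0, 200000.0),
    "lavi": (5.0, 200.0),
    "lvmi": (20.0, 400.0),
    "e_over_eprime": (1.0, 80.0),
    "septal_eprime": (0.5, 25.0),
    "trv": (0.5, 8.0),
    "gls": (0.5, 40.0),
}

#: Test-set composition: 108 NoHF and 490 HF (199 / 63 / 228) of 598.
TEST_SET_COUNTS = {Diagnosis.NoHF: 108, Diagnosis.HFrEF: 199,
                   Diagnosis.HFmrEF: 63, Diagnosis.HFpEF: 228}


def table1_default_spec(n: int = 598, seed: int = 0,
                        missingness: Optional[dict[str, float]] = None) -> CohortSpec:
    """The built-in cohort specification.

    Class priors follow the test-set composition; per-class continuous
    means/SDs, binary prevalences and the LVEF phenotype truncations are
    the published characteristics of that cohort.  Missingness defaults
    to zero everywhere.
    """
    total = sum(TEST_SET_COUNTS.values())
    priors = {dx: c / total for dx, c in TEST_SET_COUNTS.items()}
    classes: dict[Diagnosis, ClassSpec] = {}
    for dx in Diagnosis:
        continuous: dict[str, ContinuousParams] = {}
        for attr, per_class in _CONTINUOUS.items():
            mean, sd = per_class[dx]
            if attr == "lvef":
                lo, hi, hi_open = _LVEF_TRUNC[dx]
            else:
                lo, hi = _TRUNC_DEFAULT[attr]
                hi_open = False
            family = "lognormal" if attr == "nt_probnp" else "normal"
            continuous[attr] = ContinuousParams(mean, sd, lo, hi, hi_open, family)
        binary = {attr: per_class[dx] for attr, per_class in _BINARY.items()}
        classes[dx] = ClassSpec(continuous, binary)
    spec = CohortSpec(priors, classes, n=n, seed=seed,
                      missingness=dict(missingness or {}))
    return spec.validate()


def generate_cohort(spec: CohortSpec,
                    schema: Optional[AttributeSchema] = None) -> list[PatientRecord]:
    """Draw a cohort: class from the priors, attributes from the class's
    generative distributions, then Missing values injected per attribute.
    Identical specs (including seed) yield identical cohorts."""
    schema = schema or default_schema()
    spec.validate(schema)
    rng = np.random.default_rng(spec.seed)
    order = list(Diagnosis)
    priors = np.array([spec.class_priors.get(dx, 0.0) for dx in order])
    labels = rng.choice(len(order), size=spec.n, p=priors)

    width = max(4, len(str(max(spec.n, 1))))
    records = [PatientRecord(f"P{i + 1:0{width}d}", {a.name: None for a in schema},
                             order[labels[i]]) for i in range(spec.n)]
    for ci, dx in enumerate(order):
        idx = np.flatnonzero(labels == ci)
        if idx.size == 0:
            continue
        cls = spec.classes[dx]
        for attr in schema:
            if attr.name in cls.continuous:
                vals = cls.continuous[attr.name].sample(idx.size, rng)
                for i, v in zip(idx, vals):
                    records[i].values[attr.name] = float(v)
            elif attr.name in cls.binary:
                draws = rng.random(idx.size) < cls.binary[attr.name]
                for i, v in zip(idx, draws):
                    records[i].values[attr.name] = bool(v)
    if any(rate > 0 for rate in spec.missingness.values()):
        records = inject_missingness(records, spec.missingness, seed=spec.seed + 1)
    return records


def inject_missingness(records: Sequence[PatientRecord], rates: dict[str, float],
                       seed: int, schema: Optional[AttributeSchema] = None) -> list[PatientRecord]:
    """Independently replace each present value by Missing with its
    attribute's rate (MCAR).  Already-Missing values stay Missing; the
    input records are not mutated."""
    schema = schema or default_schema()
    for name, rate in rates.items():
        if name not in schema:
            raise SchemaError(f"missingness rate for unknown attribute {name!r}")
        if not (0.0 <= rate <= 1.0):
            raise CohortSpecError(f"missingness rate {rate} for {name!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = [PatientRecord(r.patient_id, dict(r.values), r.gold_diagnosis) for r in records]
    for name in schema.names:  # fixed draw order for reproducibility
        rate = rates.get(name, 0.0)
        draws = rng.random(len(out))
        if rate <= 0:
            continue
        for rec, u in zip(out, draws):
            if u < rate:
                rec.values[name] = None
    return out
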