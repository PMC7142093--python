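"""Exception hierarchy shared across the package."""


class HfdxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HfdxError):
    """A table or rate map refers to attributes the schema does not define."""


class ValidationError(HfdxError):
    """A value violates its attribute's kind or valid range."""


class KnowledgeModelError(HfdxError):
    """A decision tree or rule base violates its structural invariants."""


class ConfigError(HfdxError):
    """Invalid threshold or hyper-parameter configuration."""


class NAClassificationError(HfdxError):
    """A scalar classifier was handed a Missing value it cannot route."""


class CohortSpecError(HfdxError):
    """A generative cohort specification is inconsistent."""


class HybridizationError(HfdxError):
    """Grafting produced a structurally invalid knowledge model."""


class EvaluationError(HfdxError):
    """Evaluation inputs are unusable (length mismatch, nothing covered)."""
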