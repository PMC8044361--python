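"""Exception types shared across the package."""


class DfmError(Exception):
    """Base class for all package errors."""


class RuleParseError(DfmError):
    """A fuzzy-rule string does not follow the documented grammar, or
    references an unknown variable or term."""


class ModelValidationError(DfmError):
    """A model violates structural invariants; carries the diagnostics."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        super().__init__("invalid model:\n" + "\n".join(f"  - {d}" for d in self.diagnostics))


class EvaluationError(DfmError):
    """Rule evaluation failed (e.g. a state entry is missing)."""


class PerturbationError(DfmError):
    """A perturbation is inconsistent with the model or with itself."""


class ModelNotAttachedError(DfmError):
    """A problem definition was asked to simulate before a rule base
    (a full model) was attached to it."""
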