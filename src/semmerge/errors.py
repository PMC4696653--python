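"""Exception hierarchy shared across the package."""


class SemMergeError(Exception):
    """Base class for all package-specific errors."""


class ExpressionError(SemMergeError):
    """Malformed infix expression or unsupported construct."""


class UnitError(SemMergeError):
    """Unknown unit, bad unit definition, or incommensurable conversion."""


class ModelError(SemMergeError):
    """Structurally invalid model or illegal model edit."""


class AnnotationError(SemMergeError):
    """Ill-formed composite annotation."""


class OverlapError(SemMergeError):
    """Illegal overlap-report operation (e.g. duplicate manual mapping)."""


class MergeError(SemMergeError):
    """Unsatisfiable resolution set or inconsistent merge request."""


class SimulationError(SemMergeError):
    """Compilation or integration failure (cycles, non-finite values)."""
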