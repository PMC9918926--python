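"""Exception hierarchy for eitmap."""


class EitmapError(Exception):
    """Base class for all eitmap errors."""


class ConfigurationError(EitmapError):
    """Invalid user-supplied configuration (electrode layout, method spec, ...)."""


class ResolutionError(EitmapError):
    """Meshing failed or produced unacceptable quality at the requested edge length."""


class ValidationError(EitmapError):
    """A data structure or file violates its invariants."""


class MeshParseError(ValidationError):
    """A mesh file could not be parsed; carries the offending line number."""

    def __init__(self, path, line_no, message):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class ProtocolError(EitmapError):
    """Invalid injection/measurement protocol."""


class SolverError(EitmapError):
    """Forward-problem linear solve failed (singular or inconsistent system)."""


class GeneratorError(EitmapError):
    """Phantom generation could not satisfy its geometric constraints."""


class OptimizationError(EitmapError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
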