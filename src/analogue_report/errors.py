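"""Exception types shared across the package."""


class InsufficientDataError(ValueError):
    """Too few trials, or a degenerate design, for the requested fit."""


class ConvergenceError(RuntimeError):
    """Optimizer failed on every restart; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(ValueError):
    """An input table does not conform to the expected column schema."""
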