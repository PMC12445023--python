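"""Structured errors raised across the pipeline.

Every error carries a short machine-readable ``code`` so callers (and the
CLI) can branch on failure modes without parsing messages.
"""

from __future__ import annotations


class TwinscreenError(Exception):
    """Base class; ``code`` is a stable short token."""

    code = "error"

    def __init__(self, message: str, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class ValidationError(TwinscreenError):
    code = "validation"


class EmptyLibraryError(TwinscreenError):
    code = "empty_library"


class NoExpressionError(TwinscreenError):
    code = "no_expression"


class UnknownInputError(TwinscreenError):
    code = "unknown_input"


class DivergedError(TwinscreenError):
    code = "diverged"


class NoConvergedRunsError(TwinscreenError):
    code = "no_converged_runs"


class NoContrastError(TwinscreenError):
    code = "no_contrast"


class DegeneratePanelError(TwinscreenError):
    code = "degenerate_panel"


class ZeroTumorAucError(TwinscreenError):
    code = "zero_tumor_auc"


class ConfigError(TwinscreenError):
    code = "config"
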