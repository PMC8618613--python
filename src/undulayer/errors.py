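"""Exception hierarchy for undulayer.

All analysis-level failures derive from :class:`UndulayerError` so callers can
catch one base class; the subclasses mirror the kinds of contract violations
the pipeline distinguishes (bad file, bad role assignment, bad parameter,
underdetermined analysis, degenerate geometry, failed fit).
"""


class UndulayerError(Exception):
    """Base class for all undulayer errors."""


class FormatError(UndulayerError):
    """A coordinate file does not parse under the declared format."""


class RoleError(UndulayerError):
    """An atom cannot be assigned a semantic role, or roles are inconsistent."""


class ParameterError(UndulayerError, ValueError):
    """An operation was called with an invalid parameter."""


class AnalysisError(UndulayerError):
    """The data do not support the requested analysis (e.g. no bulk plateau)."""


class GeometryError(UndulayerError):
    """Degenerate geometry (e.g. zero-length molecular axis)."""


class FitError(UndulayerError):
    """Nonlinear fit failed to converge; carries the best residual found."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual
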