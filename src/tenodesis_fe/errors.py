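"""Exception hierarchy shared across the package."""


class TenodesisError(Exception):
    """Base class for all package errors."""


class GeometryError(TenodesisError, ValueError):
    """Invalid or degenerate geometric input."""


class DegenerateLandmarkError(GeometryError):
    """Anatomical landmarks that coincide or otherwise carry no information."""


class MaterialError(TenodesisError, ValueError):
    """Invalid constitutive parameters or stress-strain data."""


class FitError(MaterialError):
    """Curve fitting failed to converge; carries the best parameters found."""

    def __init__(self, message, best_params=None, residual=None):
        super().__init__(message)
        self.best_params = best_params
        self.residual = residual


class ProtocolError(TenodesisError, ValueError):
    """Inconsistent loading-protocol request (tensions, fixation angles, ranges)."""


class FebValidationError(TenodesisError, ValueError):
    """Model spec fails referential integrity; lists every violation found."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "model spec validation failed:\n  - " + "\n  - ".join(self.violations)
        )


class FebParseError(TenodesisError, ValueError):
    """Malformed or unsupported solver deck."""


class AnalysisError(TenodesisError, ValueError):
    """Invalid analysis input (empty windows, disjoint grids, missing rows)."""
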