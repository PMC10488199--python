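"""Exception hierarchy shared across the package."""


class PumpLipidError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PumpLipidError, ValueError):
    """A generator or stage configuration violates its invariants."""


class InsufficientDataError(PumpLipidError):
    """Too few samples in a required window or group."""


class DegenerateTraceError(PumpLipidError):
    """A trace cannot be normalized (non-positive reference intensity)."""


class DegenerateDataError(PumpLipidError):
    """Input data make the requested statistic undefined (e.g. zero variance)."""


class FitFailureError(PumpLipidError):
    """Nonlinear fit failed to converge; carries diagnostics.

    Attributes
    ----------
    diagnostics : dict
        Starting values tried and the solver messages collected.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FormatError(PumpLipidError):
    """A file does not conform to its expected on-disk format."""


class MappingError(PumpLipidError):
    """A residue number cannot be mapped into an alignment."""


class AlignmentError(PumpLipidError):
    """Rigid-body superposition is ill-posed (too few / collinear beads)."""


class SelectionError(PumpLipidError):
    """A bead/atom selection matched nothing."""
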