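"""Exception types shared across the package."""


class AudioMarkersError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(AudioMarkersError, ValueError):
    """A stimulus/simulation specification violates its invariants."""


class AlignmentError(AudioMarkersError, ValueError):
    """Stimulus rates cannot be aligned (e.g. AM minima vs phase transitions)."""


class UndefinedPhaseError(AudioMarkersError, ValueError):
    """Demodulation requested on a signal with no energy at the carrier."""


class NormalizationError(AudioMarkersError, ValueError):
    """A normalization denominator is zero or negative."""


class NoPickError(AudioMarkersError, ValueError):
    """No peak/trough pair could be identified in the search window."""


class ConvergenceError(AudioMarkersError, RuntimeError):
    """An adaptive track failed to accrue its reversals within the trial cap."""


class SingularDesignError(AudioMarkersError, ValueError):
    """Regression design matrix is rank deficient."""

    def __init__(self, columns, msg=None):
        self.columns = list(columns)
        super().__init__(msg or f"collinear/degenerate design columns: {self.columns}")
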