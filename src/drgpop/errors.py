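"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class DegenerateBaselineError(ValidationError):
    """Baseline fluorescence F0 <= 0: dF/F is undefined for this cell."""


class PlacementError(RuntimeError):
    """Somata could not be placed in the imaging field without overlap."""


class EmptyFilterError(ValidationError):
    """A cell filter selected zero cells; fractions would divide by zero."""
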