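"""Exception hierarchy for CPET data handling and threshold detection."""


class CPETError(Exception):
    """Base class for all package errors."""


class FormatError(CPETError):
    """A delimited-text export is structurally unusable (e.g. missing columns)."""


class ValidationError(CPETError):
    """Data violate a series invariant (grid, positivity, channel consistency)."""


class DetectionError(CPETError):
    """Threshold detection cannot run (e.g. test too short)."""


class SimulationError(CPETError):
    """Simulation parameters are inconsistent with producing a usable test."""
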