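"""Exception hierarchy for the CBMM simulator."""


class CbmmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CbmmError):
    """Invalid, inconsistent or unit-less configuration input."""


class GeometryError(CbmmError):
    """Degenerate or non-manifold mesh geometry."""


class StateError(CbmmError):
    """Invalid simulation state (NaN positions, missing contact map, ...)."""
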