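"""Package-specific exception types."""


class DbtmcError(Exception):
    """Base class for all package errors."""


class SizeError(DbtmcError, ValueError):
    """Grid or input too small for the requested operation."""


class PlacementError(DbtmcError, ValueError):
    """Lesion placement outside the allowed region."""


class SelectionError(DbtmcError, ValueError):
    """Invalid slice-selection request."""


class ParameterError(DbtmcError, ValueError):
    """Invalid parameter value for an image operation."""


class ShapeError(DbtmcError, ValueError):
    """A network layer chain produces a non-positive spatial extent."""
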