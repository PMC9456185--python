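"""Exception hierarchy shared by all analysis stages."""


class HostGuestError(Exception):
    """Base class for all package errors."""


class InvalidInputError(HostGuestError, ValueError):
    """Input violates a structural precondition (too few points, empty selection, ...)."""


class DomainError(HostGuestError, ValueError):
    """Numerically valid input outside the mathematical domain of an operation."""


class SchemaError(HostGuestError, ValueError):
    """Tabular input whose columns or cell types do not match the expected schema."""


class ParseError(HostGuestError, ValueError):
    """Malformed structured file (PDB/XYZ); carries file position context."""

    def __init__(self, message: str, line: int | None = None, frame: int | None = None):
        ctx = []
        if frame is not None:
            ctx.append(f"frame {frame}")
        if line is not None:
            ctx.append(f"line {line}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.line = line
        self.frame = frame


class TopologyError(HostGuestError, ValueError):
    """Topology missing required sites or with inconsistent unit indexing."""


class DegenerateGeometryError(HostGuestError, ValueError):
    """Coordinate selection too degenerate (collinear/coincident) for superposition."""
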