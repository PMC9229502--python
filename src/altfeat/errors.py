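"""Exception hierarchy shared across the package."""


class AltfeatError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AltfeatError):
    """An input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" in {path}"
        if line is not None:
            loc += f" at line {line}"
        super().__init__(message + loc)


class LookupFailure(AltfeatError):
    """A gene/transcript query did not resolve to exactly one record."""


class ProjectionError(AltfeatError):
    """A protein-coordinate feature cannot be placed on its transcript's CDS."""


class DataError(AltfeatError):
    """Inputs are structurally valid but semantically unusable."""
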