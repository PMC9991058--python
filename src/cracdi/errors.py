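"""Exception types shared across the package."""


class CracdiError(Exception):
    """Base class for package errors."""


class InvalidParameterError(CracdiError, ValueError):
    """A physical parameter is outside its valid domain."""


class DegenerateModelError(CracdiError, ValueError):
    """A kinetic model has no well-defined behaviour (e.g. all rates zero)."""


class ProtocolError(CracdiError, ValueError):
    """A voltage protocol does not have the shape an operation requires."""


class WindowError(CracdiError, ValueError):
    """An analysis window falls outside the trace or is degenerate."""


class AmbiguousCrossingError(CracdiError, ValueError):
    """An I-V curve crosses zero more than once; candidates attached."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            f"I-V curve crosses zero {len(self.candidates)} times: "
            f"{self.candidates}"
        )


class TraceFormatError(CracdiError, ValueError):
    """A trace file violates the on-disk format contract."""


class ConfigError(CracdiError, ValueError):
    """A configuration document contains unknown or invalid keys."""
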