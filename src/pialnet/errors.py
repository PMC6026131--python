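"""Exception hierarchy shared across the package."""


class PialnetError(Exception):
    """Base class for all package errors."""


class FormatError(PialnetError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(PialnetError):
    """An in-memory object violates a structural invariant."""


class GenerationError(PialnetError):
    """Synthetic-data generation could not satisfy the requested parameters."""


class DegenerateNetworkError(GenerationError):
    """A generated network would contain no vessels at all."""


class NoBackboneError(PialnetError):
    """A network has no cycles, so no backbone/offshoot decomposition exists."""
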