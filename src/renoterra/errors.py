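"""Exception hierarchy for renoterra.

All package errors derive from :class:`RenoterraError` so callers (and the CLI)
can catch one base class and map it to a nonzero exit code.
"""


class RenoterraError(Exception):
    """Base class for all renoterra errors."""


class FormatError(RenoterraError):
    """A file could not be parsed, or its header is ambiguous/unsupported."""


class ValidationError(RenoterraError):
    """Input violates a documented contract (duplicate names, bad labels, ...)."""


class DegenerateInputError(RenoterraError):
    """Structurally valid input that is empty or otherwise unusable (e.g. a mask
    with no foreground voxels)."""


class ConsistencyError(RenoterraError):
    """Two inputs that must agree do not (e.g. a labelmap referencing an
    endpoint id that does not exist in the fiducial set)."""


class PairingError(ValidationError):
    """Reader A and reader B measurements could not be matched by label."""


class GenerationError(RenoterraError):
    """A phantom specification cannot be realised on the requested grid."""
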