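"""Exception hierarchy shared across the pipeline.

Three failure classes are distinguished so callers can react differently:
malformed files (:class:`FormatError`), data that parses but violates a
domain invariant (:class:`ValidationError`), and inputs that are valid but
unusable for a particular computation (:class:`InputError`), e.g. a series
too short to difference or a stationary tip whose path distance is zero.
"""


class MicroskillError(Exception):
    """Base class for all pipeline errors."""


class FormatError(MicroskillError):
    """A file does not match the expected on-disk format (e.g. missing column)."""


class ValidationError(MicroskillError):
    """Parsed data violates a domain invariant (e.g. non-monotone frames)."""


class InputError(MicroskillError):
    """Input is well-formed but unusable for the requested computation."""


class DegenerateInputError(InputError):
    """The computation is mathematically undefined on this input
    (zero variance, zero path distance, ...)."""
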