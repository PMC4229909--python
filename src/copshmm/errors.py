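"""Exception hierarchy for copshmm.

All package errors derive from :class:`CopsError` so callers (and the CLI)
can distinguish usage/data problems from genuine bugs.
"""


class CopsError(Exception):
    """Base class for all copshmm errors."""


class FormatError(CopsError):
    """A model or sequence file violates the expected on-disk format."""


class ValidationError(CopsError):
    """An in-memory object violates a probabilistic or structural invariant."""


class UnsupportedAlphabetError(CopsError):
    """The requested residue alphabet is not supported."""


class QuantizationOverflowError(CopsError):
    """A finite score cannot be represented in the signed 16-bit range."""


class SizeError(CopsError):
    """An exhaustive operation was asked to run beyond its safety bounds."""
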