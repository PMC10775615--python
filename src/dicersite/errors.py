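"""Exception hierarchy.

Everything raised on bad user input derives from :class:`DicersiteError`,
so the CLI can map any of them to a one-line diagnostic and exit code 1.
"""


class DicersiteError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DicersiteError):
    """A file does not conform to its on-disk format (names the line/record)."""


class ValidationError(DicersiteError):
    """Parsed data violates a domain invariant (lengths, alphabets, brackets)."""


class BoundaryError(DicersiteError):
    """A requested window or coordinate falls outside the sequence."""


class EncodingError(DicersiteError):
    """A symbol outside the encoder's alphabet was encountered."""


class CountError(DicersiteError):
    """A split or selection requested more rows than are available."""


class CheckpointError(DicersiteError):
    """A checkpoint file is missing, versioned wrong, or mismatches its spec."""
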