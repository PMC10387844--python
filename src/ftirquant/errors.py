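"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`FtirError` so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class FtirError(Exception):
    """Base class for all pipeline errors."""


class ParseError(FtirError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(FtirError):
    """An input violates a structural invariant (duplicates, bounds, shapes)."""


class CoverageError(FtirError):
    """A spectrum does not cover a requested wavenumber span."""


class RangeError(FtirError):
    """A resampling grid extends beyond the spectrum span."""


class NormalizationError(FtirError):
    """Reference-band intensity is non-positive; the spectrum is degenerate."""


class DegenerateSpectrumError(FtirError):
    """A metric denominator is zero or negative."""


class UnsupportedDialectError(ParseError):
    """A JCAMP-DX feature (compression, units) outside the supported subset."""
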