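"""Exception types shared across the pipeline."""


class CocomixError(Exception):
    """Base class for all package errors."""


class ConfigError(CocomixError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(CocomixError, ValueError):
    """Malformed in-memory data (wrong dtype, negative counts, shape mismatch...)."""


class ParseError(CocomixError, ValueError):
    """Malformed input file; message names the offending line or id."""


class NormalizationError(CocomixError, RuntimeError):
    """Size-factor computation impossible (no gene expressed in all samples)."""


class InsufficientReadsError(CocomixError, RuntimeError):
    """A read pool holds fewer records than its sampling quota."""


class SegmentationError(CocomixError, RuntimeError):
    """No structures detectable in an image channel."""


class GenerationError(CocomixError, RuntimeError):
    """Synthetic-data construction failed (e.g. fragments cannot be placed)."""


class TestError(CocomixError, RuntimeError):
    """A statistical test is undefined for the given input."""


class CoverageError(CocomixError, ValueError):
    """No overlap between a signature and an external matrix."""


class ReferenceError_(CocomixError, KeyError):
    """A composition row references a sample that does not exist."""
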