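"""Exception hierarchy.

Every error raised by this package derives from :class:`GfscoreError`, so
pipelines can catch one type at the boundary while tests can assert on the
specific failure mode.
"""


class GfscoreError(Exception):
    """Base class for all errors raised by gfscore."""


class IdentifierError(GfscoreError):
    """Duplicate or unknown gene/sample identifiers."""


class ParseError(GfscoreError):
    """Malformed input file (non-numeric cell, bad row, missing value)."""


class SchemaError(GfscoreError):
    """Input table lacks a required column."""


class AlignmentError(GfscoreError):
    """Expression matrix and annotation share no samples."""


class ParameterError(GfscoreError):
    """Invalid user-supplied parameter (thresholds, fractions, indices)."""


class DegenerateSampleError(GfscoreError):
    """A sample is constant (or zero) where the transform needs spread."""


class EvaluationError(GfscoreError):
    """An evaluation stage cannot run (single cluster, too few genes...)."""


class SplitError(GfscoreError):
    """Stratified splitting impossible (a phenotype with one sample)."""
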