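"""Exception hierarchy for the pipeline.

Every error raised deliberately by this package derives from
:class:`PipelineError`, so callers (and the CLI) can distinguish
anticipated data problems from genuine bugs.
"""


class PipelineError(Exception):
    """Base class for all anticipated pipeline errors."""


class FormatError(PipelineError):
    """A file does not conform to its declared format."""


class CoordinateError(FormatError):
    """Invalid genomic coordinates (e.g. start >= end)."""


class PloidyError(FormatError):
    """A genotype call is not diploid."""


class ConfigError(PipelineError):
    """A configuration value violates its invariant."""


class AlignmentError(PipelineError):
    """Sample sets of the input matrices do not match."""


class CollinearityError(PipelineError):
    """The covariate design matrix is rank deficient."""


class CapacityError(PipelineError):
    """A simulated genome cannot fit the requested features."""


class PlantingError(PipelineError):
    """No eligible SNP/gene available for a planted effect."""


class SizeFactorError(PipelineError):
    """Median-of-ratios size factors are undefined for these counts."""
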