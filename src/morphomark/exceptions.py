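"""Exception hierarchy for the morphomark pipeline."""


class MorphomarkError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(MorphomarkError):
    """A cohort or atlas design violates its invariants."""


class FormatError(MorphomarkError):
    """A file could not be read or parsed as the expected format."""


class DesignMatrixError(MorphomarkError):
    """GLM design matrix is rank deficient or otherwise unusable."""


class DegenerateTrainingError(MorphomarkError):
    """A classifier was handed a training set it cannot learn from
    (e.g. a single class)."""


class MetricError(MorphomarkError):
    """Performance metrics are undefined for the given labels."""


class ZeroVarianceError(MorphomarkError):
    """Correlation requested on a constant vector."""


class PipelineConfigError(MorphomarkError):
    """Pipeline configuration failed validation."""
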