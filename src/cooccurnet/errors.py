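"""Named exceptions and warnings raised across the pipeline.

Every validation failure has its own class so callers (and the CLI) can
report which rule was violated rather than guessing from a message.
"""


class CooccurnetError(Exception):
    """Base class for all package errors."""


class DuplicateIdError(CooccurnetError):
    """A taxon or sample identifier occurs more than once."""


class NegativeValueError(CooccurnetError):
    """An abundance value is negative."""


class MissingMetadataError(CooccurnetError):
    """A sample in the abundance table has no metadata row."""


class EmptyFilterError(CooccurnetError):
    """A taxa filter removed every taxon."""


class ThresholdError(CooccurnetError):
    """Correlation threshold outside (0, 1]."""


class DesignError(CooccurnetError):
    """Invalid synthetic-design parameters."""


class UnknownCategoryError(CooccurnetError):
    """A function-category name is not one of the recognised categories."""


class UndefinedVulnerabilityError(CooccurnetError):
    """Vulnerability requested for a graph with zero global efficiency."""


class UndefinedDissimilarityError(CooccurnetError):
    """Dissimilarity requested for two empty networks."""


class UndefinedDistanceError(CooccurnetError):
    """Bray-Curtis distance undefined (a sample with all-zero abundances)."""


class UndefinedCorrelationError(CooccurnetError):
    """Mantel correlation undefined (constant off-diagonal distances)."""


class GroupSizeError(CooccurnetError):
    """ANOSIM group with fewer than two samples."""


class PartitionError(CooccurnetError):
    """A module partition does not cover the network it is paired with."""


class ZeroVarianceWarning(UserWarning):
    """Taxa with zero variance were excluded before correlation."""


class CoverageWarning(UserWarning):
    """Taxonomy does not cover every networked taxon; missing binned as Others."""


class EmptyNetworkWarning(UserWarning):
    """An operation received an empty network and returned a degenerate result."""
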