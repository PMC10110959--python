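"""Exception hierarchy for modewalk.

All package errors derive from :class:`ModewalkError` so callers can catch
one type at pipeline boundaries while tests can assert on specific failures.
"""


class ModewalkError(Exception):
    """Base class for all modewalk errors."""


class FormatError(ModewalkError):
    """Malformed input table (e.g. a required column is missing)."""


class ValidationError(ModewalkError):
    """Input data violates a structural invariant (e.g. duplicate timestamps)."""


class ConsistencyError(ModewalkError):
    """Cross-referenced records disagree (e.g. a label for an unknown track)."""


class ConfigurationError(ModewalkError):
    """Unknown or inconsistent configuration value."""


class TooShortError(ModewalkError):
    """Trajectory or segment has too few points for the requested operation."""


class SizeError(ModewalkError):
    """A size/duration precondition is violated."""


class RangeError(ModewalkError):
    """A numeric argument is outside its admissible range."""


class SpecificationError(ModewalkError):
    """An operation's parameter specification is self-contradictory."""


class UndefinedShapeError(ModewalkError):
    """Shape descriptor undefined (degenerate, e.g. all points coincide)."""


class UndefinedScoreError(ModewalkError):
    """Silhouette score undefined (fewer than two clusters)."""


class ClusteringError(ModewalkError):
    """Clustering cannot proceed (e.g. all points identical)."""


class StratificationError(ModewalkError):
    """A pseudo-class is absent from the training split."""


class AmbiguousNamingError(ModewalkError):
    """Cluster-to-mode naming is ambiguous (tied summary statistics)."""


class FitError(ModewalkError):
    """A curve fit cannot be performed on the given data."""


class NoDataError(ModewalkError):
    """An estimator received an empty pool."""


class ModelIOError(ModewalkError):
    """A persisted model file is unreadable or has a mismatched version."""
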