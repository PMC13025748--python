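"""Exception hierarchy for culinet.

All package-specific failures derive from :class:`CulinetError` so callers can
catch one base class at pipeline boundaries while tests can assert on the
specific condition.
"""


class CulinetError(Exception):
    """Base class for all culinet errors."""


class SchemaError(CulinetError):
    """Input table is missing required columns or has an unusable layout."""


class EmptyCorpusError(CulinetError):
    """The input table or recipe list contains no usable rows."""


class ValidationError(CulinetError):
    """A value violates a declared invariant (empty name, bad label, ...)."""


class UnknownCourseError(CulinetError):
    """A raw course label has no entry in the course harmonization map."""


class UnmappedIngredientError(CulinetError):
    """Normalized ingredients with no category in the taxonomy."""

    def __init__(self, offenders):
        self.offenders = sorted(set(offenders))
        super().__init__(
            "ingredients missing from taxonomy: " + ", ".join(self.offenders)
        )


class EmptySubsetError(CulinetError):
    """Requested (cuisine, course) subset contains zero recipes."""


class UndefinedMetricError(CulinetError):
    """Metric has no defined value on this network (e.g. density with n < 2)."""


class UndefinedSimilarityError(CulinetError):
    """Edge Jaccard is undefined: both edge sets are empty."""


class InsufficientDataError(CulinetError):
    """Too few recipes for the requested resampling scheme."""


class GenerationError(CulinetError):
    """Synthetic corpus constraints could not be satisfied within retry budget."""


class ConvergenceError(CulinetError):
    """Iterative solver (eigenvector power iteration) failed to converge."""
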