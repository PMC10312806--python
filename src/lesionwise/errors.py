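"""Exception hierarchy shared across the package."""


class LesionwiseError(Exception):
    """Base class for all package errors."""


class FormatError(LesionwiseError):
    """Input file is not a valid integer label volume."""


class ValidationError(LesionwiseError):
    """Input violates the label convention or a parameter bound."""


class ComparisonError(LesionwiseError):
    """A ground-truth/prediction pair is not comparable (shape/spacing)."""


class UndefinedDistanceError(LesionwiseError):
    """A surface distance was requested for an empty mask."""


class DegenerateCohortError(LesionwiseError):
    """Cohort-level rates requested for a cohort with no evaluable lesions."""


class IncompleteGridError(LesionwiseError):
    """The team x subject x region x metric score grid has missing cells."""

    def __init__(self, missing):
        self.missing = list(missing)
        preview = ", ".join(map(str, self.missing[:10]))
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"score grid is missing cells: {preview}{more}")


class PackingError(LesionwiseError):
    """Phantom lesion placement failed after bounded retries."""
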