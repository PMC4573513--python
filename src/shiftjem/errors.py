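"""Exception hierarchy for the shiftjem pipeline.

Configuration objects are pydantic models, so malformed configuration raises
:class:`pydantic.ValidationError` (which names the offending field); the
classes below cover failures arising from data rather than configuration.
"""


class ShiftJemError(Exception):
    """Base class for all shiftjem-specific errors."""


class DomainError(ShiftJemError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class LinkageError(ShiftJemError):
    """Occupation-code linkage failed structurally (bad code, sex mismatch)."""


class DataIntegrityError(ShiftJemError):
    """Records violate a structural invariant (duplicate ids, mixed sexes)."""


class DataError(ShiftJemError):
    """The data cannot support the requested estimation."""


class SingularDesignError(DataError):
    """The design matrix is rank deficient.

    ``collinear_terms`` names the columns that are linearly dependent on the
    preceding ones.
    """

    def __init__(self, collinear_terms):
        self.collinear_terms = list(collinear_terms)
        super().__init__(
            "design matrix is rank deficient; collinear terms: "
            + ", ".join(self.collinear_terms)
        )


class NotConvergedError(ShiftJemError):
    """An iterative fit did not converge and the caller requires convergence."""
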