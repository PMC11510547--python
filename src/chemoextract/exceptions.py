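"""Exception hierarchy for chemoextract.

All library errors derive from :class:`ChemoextractError` so callers can
catch one base class; validation problems raise :class:`SchemaError`.
"""


class ChemoextractError(Exception):
    """Base class for all chemoextract errors."""


class UnsupportedDesignError(ChemoextractError):
    """Requested design is outside the supported family (3 factors only)."""


class SingularDesignError(ChemoextractError):
    """Model matrix is rank deficient; carries the collinear term labels."""

    def __init__(self, collinear_terms):
        self.collinear_terms = list(collinear_terms)
        super().__init__(
            "model matrix is rank deficient; collinear terms: "
            + ", ".join(self.collinear_terms)
        )


class NoPureErrorError(ChemoextractError):
    """No replicated condition available, so pure error cannot be estimated."""


class DegenerateVarianceError(ChemoextractError):
    """Pooled variance is zero; t-tests on the coefficients are undefined."""


class ZeroVarianceError(ChemoextractError):
    """A column is constant and cannot be autoscaled."""

    def __init__(self, column):
        self.column = column
        super().__init__(f"column {column!r} has zero variance and cannot be autoscaled")


class FlatSpectrumError(ChemoextractError):
    """A spectrum has zero standard deviation; SNV is undefined for it."""

    def __init__(self, run_id):
        self.run_id = run_id
        super().__init__(f"spectrum of run {run_id!r} is flat (sd = 0); SNV undefined")


class SchemaError(ChemoextractError):
    """An input table does not conform to the expected schema."""


class OutOfDomainWarning(UserWarning):
    """A natural-unit value lies outside the factor's studied range."""
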