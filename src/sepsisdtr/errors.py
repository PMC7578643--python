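"""Exception hierarchy for cohort validation and regime estimation."""


class SepsisDTRError(Exception):
    """Base class for all package errors."""


class SchemaError(SepsisDTRError):
    """A cohort table violates the declared column/row schema."""


class MalformedTrajectoryError(SepsisDTRError):
    """A patient trajectory is internally inconsistent (day gaps, bad outcome times)."""


class MissingDataError(SepsisDTRError):
    """A required covariate is absent; carries patient/day/variable context."""

    def __init__(self, message, patient_id=None, day=None, variable=None):
        super().__init__(message)
        self.patient_id = patient_id
        self.day = day
        self.variable = variable


class DegenerateTreatmentError(SepsisDTRError):
    """All records in a stage received the same treatment arm."""


class CollinearityError(SepsisDTRError):
    """The stage design matrix is rank deficient; lists aliased terms."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class NoVertexError(SepsisDTRError):
    """A rule lacks a concave quadratic term for the requested variable."""


class ConfigurationError(SepsisDTRError):
    """A run configuration or regime document is incomplete or inconsistent."""
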