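"""Exception hierarchy for the altered-self analysis."""


class AlteredSelfError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AlteredSelfError):
    """A required column is missing from an input table."""


class ValidationError(AlteredSelfError):
    """A row or field violates the peptide-record contract."""


class ConflictError(AlteredSelfError):
    """Duplicate peptide sequences carry contradictory annotations."""


class UndefinedFractionError(AlteredSelfError):
    """A fraction was requested with a zero denominator."""


class UndefinedCategoryError(AlteredSelfError):
    """A change category was requested for a (0, 0) density pair."""


class EmptyInputError(AlteredSelfError):
    """An operation requiring a nonempty repertoire or table got an empty one."""


class ParameterError(AlteredSelfError):
    """A parameter is outside its admissible range."""


class CapacityError(AlteredSelfError):
    """A uniqueness constraint cannot be satisfied (pigeonhole violation)."""
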