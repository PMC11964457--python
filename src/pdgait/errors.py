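"""Exception and warning types used across the package."""


class PdgaitError(Exception):
    """Base class for package errors."""


class ParseError(PdgaitError):
    """A walk file or table could not be parsed."""


class SchemaError(PdgaitError):
    """A tabular input is missing required columns or violates the schema."""


class ValidationError(PdgaitError):
    """Loaded data violates a hard invariant (e.g. non-monotone time)."""


class TrainingDiverged(PdgaitError):
    """Optimisation produced a non-finite loss."""


class TotalsMismatchWarning(UserWarning):
    """A total-force column disagrees with the sum of its 8 sensors beyond tolerance."""


class DegenerateInputWarning(UserWarning):
    """An operation hit a degenerate input (zero variance, rank deficiency, ...)."""
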