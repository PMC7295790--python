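"""Exception hierarchy for culturopt.

Everything raised on bad user input derives from :class:`CulturoptError`
so callers (and the CLI) can catch one base class.
"""


class CulturoptError(Exception):
    """Base class for all culturopt errors."""


class FormatError(CulturoptError):
    """A tabular input file does not match the expected layout."""


class EmptyInputError(FormatError):
    """An input file contained no data rows."""


class MatrixValidationError(CulturoptError):
    """An incidence matrix violates a structural invariant."""


class UnknownConditionError(CulturoptError, KeyError):
    """A condition id is not present in the matrix."""


class UnknownGroupError(CulturoptError, KeyError):
    """A group tag matches no condition in the matrix."""


class CapacityError(CulturoptError):
    """An exact (exhaustive) routine was asked for an instance too large."""


class DegenerateTableError(CulturoptError):
    """A contingency table has a zero row or column margin."""


class ConsistencyError(CulturoptError):
    """Two objects that must describe the same data do not."""


class GenerationError(CulturoptError):
    """The synthetic generator could not satisfy the matrix invariants."""


class StageError(CulturoptError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
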