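"""Exception hierarchy for structural and validation failures.

Every error raised by the package derives from :class:`PiError`, so callers
(and the CLI) can distinguish validation failures from programming errors.
"""


class PiError(Exception):
    """Base class for all package-specific errors."""


class StructureError(PiError):
    """Dimensions or component shapes are inconsistent."""


class MetadataError(PiError):
    """Required cell-metadata columns are missing or invalid."""


class MembershipError(PiError):
    """A referenced cell id does not exist in the target object."""


class DuplicateNameError(PiError):
    """A child or slot name is already taken."""


class LabelAmbiguityError(PiError):
    """Overlapping children assign conflicting labels to the same cells."""

    def __init__(self, message, cell_ids=None):
        super().__init__(message)
        self.cell_ids = list(cell_ids) if cell_ids is not None else []


class ParameterError(PiError):
    """A numeric parameter is outside its valid range."""


class MissingReductionError(PiError):
    """A named reduction (or neighbor graph) is not present."""


class DegenerateScaleError(PiError):
    """Distance rescaling is undefined (all child distances are zero)."""


class ContainmentError(PiError):
    """A proportion reference does not contain the target population."""


class PlanError(PiError):
    """A synthetic fixture plan is infeasible."""


class PiWarning(UserWarning):
    """Non-fatal conditions: fallbacks, short neighbor rows, dropped rows."""
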