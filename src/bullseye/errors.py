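"""Exception types shared across the package."""


class BullseyeError(Exception):
    """Base class for package errors."""


class InvalidStateError(BullseyeError):
    """A cell or tissue violates a structural invariant (e.g. length <= 0)."""


class NoProgressError(BullseyeError):
    """A simulation exceeded its step budget without reaching the target length."""


class CellNotFoundError(BullseyeError, KeyError):
    """A cell id was requested that is not present in the tissue."""


class UndefinedRatioError(BullseyeError, ZeroDivisionError):
    """A fate region is empty, so a per-region ratio is undefined."""


class UndefinedSensitivityError(BullseyeError, ZeroDivisionError):
    """Baseline observable is zero; relative sensitivity is undefined."""


class ContiguityError(BullseyeError):
    """Pigmented cells do not form a single basal block."""

    def __init__(self, message, offending_rows=None):
        super().__init__(message)
        self.offending_rows = list(offending_rows) if offending_rows is not None else []


class EmptySelectionWarning(UserWarning):
    """A filter removed every record."""


class CoarseStepWarning(UserWarning):
    """dt times the maximum division propensity is large; discretisation is coarse."""
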