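"""Exception hierarchy shared across the package."""


class CapskelError(ValueError):
    """Base class for all domain errors raised by capskel."""


class UnknownVariableError(CapskelError):
    """A variable label is not present in the dataset."""


class DegenerateInputError(CapskelError):
    """An input symbol has no complete observations, so its channel row
    cannot be estimated."""


class AlphabetMismatchError(CapskelError):
    """Two objects that must share an alphabet do not."""


class MissingCountsError(CapskelError):
    """An operation needs raw co-occurrence counts but the tensor carries
    none (e.g., it was composed or derived from a population model)."""


class MissingConfidenceError(CapskelError):
    """An operation needs per-cell confidence bounds but the tensor has
    none."""


class MediatorAlphabetError(CapskelError):
    """A joint mediator variable has more observed symbols than the
    configured cap allows; the resulting tensor rows would be too thin to
    test."""
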