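"""Exception hierarchy shared across the package."""


class PrilloptError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PrilloptError):
    """A delimited table is structurally invalid (e.g. a required column is absent)."""


class TableParseError(PrilloptError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DomainError(PrilloptError):
    """A value lies outside its admissible domain."""


class DegenerateInputError(PrilloptError):
    """Input is formally valid but statistically degenerate (e.g. constant response)."""


class InsufficientDataError(PrilloptError):
    """Too few observations for the requested computation."""


class MassBalanceError(PrilloptError):
    """Accounted mass losses exceed the mass fed into the process."""


class TrainingDivergenceError(PrilloptError):
    """Iterative training produced a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
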