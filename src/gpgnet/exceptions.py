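"""Exception hierarchy shared across the package."""


class GpgnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GpgnetError, ValueError):
    """A parameter violates a documented precondition."""


class ContractViolationError(GpgnetError, ValueError):
    """Inputs are internally inconsistent (shape/config mismatch)."""


class AlreadyNormalizedError(GpgnetError, ValueError):
    """Normalization requested on a graph that is already normalized."""


class TrainingDivergedError(GpgnetError, RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")


class FastaParseError(GpgnetError, ValueError):
    """A FASTA file is malformed."""
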