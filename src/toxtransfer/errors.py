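"""Named exceptions raised across the package."""


class ToxTransferError(Exception):
    """Base class for all package-specific errors."""


class IncompleteDesignError(ToxTransferError):
    """A compound lacks the replicates, doses or time points the design requires."""


class GeneSetMismatchError(ToxTransferError):
    """Gene identifiers or their order disagree between two components."""


class DimensionMismatchError(ToxTransferError):
    """An input vector or matrix does not match the expected shape."""


class TrainingDivergedError(ToxTransferError):
    """Training produced a non-finite loss; the partial history is attached."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class NoLabelledCompoundsError(ToxTransferError):
    """The latent classifier was given no labelled compounds."""


class InvalidScheduleInputError(ToxTransferError):
    """Training progress outside [0, 1] passed to the reversal-scale schedule."""


class DomainCompositionError(ToxTransferError):
    """A batch or embedding set lacks the domain composition an operation needs."""


class CheckpointError(ToxTransferError):
    """A model checkpoint is corrupt or inconsistent with its content hash."""


class ConfigError(ToxTransferError):
    """A run configuration contains unknown keys or invalid values."""
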