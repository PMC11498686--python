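"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`MedifuseError`
so callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class MedifuseError(Exception):
    """Base class for all errors raised by medifuse."""


class FormatError(MedifuseError):
    """An input file could not be read or has an unsupported format."""


class ValidationError(MedifuseError):
    """Inputs violate a documented precondition (shape mismatch, bad range...)."""


class ParameterError(MedifuseError):
    """A parameter is outside its documented range."""


class DegenerateInputError(MedifuseError):
    """The input is degenerate for the requested operation (e.g. constant
    image under a mutual-information cost, zero-entropy image under a
    normalized metric)."""


class ContractViolationError(MedifuseError):
    """A pluggable component (e.g. a feature extractor) returned output that
    violates its declared contract."""


class TrainingDivergenceError(MedifuseError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, learning_rate: float):
        self.epoch = epoch
        self.learning_rate = learning_rate
        super().__init__(
            f"non-finite training loss at epoch {epoch} "
            f"(learning rate {learning_rate}); reduce the learning rate"
        )
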