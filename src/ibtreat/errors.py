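"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class ShapeError(InvalidArgumentError):
    """Array dimensions are inconsistent with the model or data."""


class InfiniteKLError(InvalidArgumentError):
    """A KL divergence is infinite (prior mass zero where posterior has mass)."""


class SchemaError(ValueError):
    """A dataset file does not match its declared schema."""


class ParseError(ValueError):
    """A dataset value could not be interpreted (e.g. non-binary treatment)."""


class DegenerateSplitError(ValueError):
    """A data split lacks treated or control units, or is unusably small."""


class DegenerateDesignError(ValueError):
    """A synthetic design ended up with an empty treatment arm."""


class AbsentBlockError(InvalidArgumentError):
    """A covariate block was requested that is systematically missing."""


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")
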