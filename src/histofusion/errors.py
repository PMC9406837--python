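"""Exception types shared across the pipeline."""


class DegenerateInputError(ValueError):
    """An input is structurally valid but numerically degenerate
    (e.g. a color channel whose mean is zero, so gray-world scaling
    would divide by zero)."""


class ConfigurationError(ValueError):
    """A configuration value names something that does not exist or
    combines options the pipeline contract forbids."""


class TrainingDivergenceError(RuntimeError):
    """Training produced a non-finite loss. Carries the epoch at which
    the divergence was detected."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")
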