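"""Exception hierarchy shared across the package."""


class MsenrichError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MsenrichError):
    """An input table is missing a required column or feature."""


class ValidationError(MsenrichError):
    """A value violates a domain invariant (off-grid EDSS, unknown id, ...)."""


class ParameterError(MsenrichError):
    """A numeric parameter is outside its admissible range."""


class StandardizationError(MsenrichError):
    """A feature cannot be standardized (zero variance on the training split)."""


class StratificationError(MsenrichError):
    """A cross-validation fold is missing one of the treatment arms."""


class DivergenceError(MsenrichError):
    """Optimization produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")
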