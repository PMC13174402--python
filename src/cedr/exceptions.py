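"""Exception hierarchy for the cedr package."""


class CedrError(Exception):
    """Base class for all cedr errors."""


class ConfigurationError(CedrError, ValueError):
    """Invalid configuration value (unknown scenario, bad noise level, ...)."""


class ValidationError(CedrError, ValueError):
    """Invalid input data (non-finite entries, shape mismatch, bad range, ...)."""


class TrainingError(CedrError, RuntimeError):
    """Autoencoder training failure (non-finite loss)."""

    def __init__(self, message: str, epoch: int | None = None,
                 learning_rate: float | None = None):
        super().__init__(message)
        self.epoch = epoch
        self.learning_rate = learning_rate


class DegenerateFitError(CedrError, RuntimeError):
    """A model fit collapsed (e.g. every sample absorbed by the noise component)."""


class NumericalError(CedrError, RuntimeError):
    """Non-finite quantity encountered during an iterative fit."""
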