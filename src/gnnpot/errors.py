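"""Exception taxonomy.

``ValidationError`` covers bad inputs and configs (CLI exit code 2);
everything else raised by the package is a runtime failure (exit code 1).
"""


class GnnPotError(Exception):
    """Base class for all package errors."""


class ValidationError(GnnPotError, ValueError):
    """Invalid user input: bad config values, malformed specs, bad shapes."""


class ParseError(GnnPotError, ValueError):
    """Malformed extended-XYZ (or other) input file."""


class UnlabeledFrameError(GnnPotError, ValueError):
    """A frame lacks the energy/force labels an operation requires."""


class UnknownElementError(GnnPotError, ValueError):
    """Element symbol or atomic number outside the supported table."""


class ModelFormatError(GnnPotError, ValueError):
    """Corrupt, tampered or version-incompatible model archive."""


class TrainingDivergenceError(GnnPotError, RuntimeError):
    """Loss or model output became non-finite during training."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"non-finite value encountered at training step {step}")
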