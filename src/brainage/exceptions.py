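"""Exception hierarchy for the brainage package."""


class BrainAgeError(Exception):
    """Base class for all domain errors raised by this package."""


class FormatError(BrainAgeError):
    """A file does not conform to the expected tabular format."""


class ValidationError(BrainAgeError):
    """Parsed values violate a domain invariant (age range, sex token, ...)."""


class TrainingError(BrainAgeError):
    """Predictor training failed, e.g. no gene passed the selection thresholds."""


class PredictionError(BrainAgeError):
    """Age prediction is impossible, e.g. every effective slope is ~0."""


class HarmonizationError(BrainAgeError):
    """No model gene could be mapped onto the target platform."""


class CalibrationError(BrainAgeError):
    """No housekeeping gene is shared between the two datasets."""


class DegenerateFitWarning(UserWarning):
    """A per-gene fit was degenerate (constant expression); slopes set to 0."""
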