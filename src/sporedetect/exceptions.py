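"""Exception hierarchy for sporedetect."""


class SporeDetectError(Exception):
    """Base class for all sporedetect errors."""


class TrainingError(SporeDetectError):
    """Too few samples to train the colour model."""


class DegenerateModelError(SporeDetectError):
    """Training samples carry no colour variation (rank-0 scatter)."""


class FormatError(SporeDetectError):
    """Input image or table is not in the expected format."""


class ConfigError(SporeDetectError):
    """A configuration value is out of its valid range."""


class PlacementError(SporeDetectError):
    """Synthetic spores could not be placed without overlap."""


class DegenerateBlobError(SporeDetectError):
    """Blob has too few pixels for the requested geometry."""
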