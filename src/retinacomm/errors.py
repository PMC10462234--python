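"""Exception hierarchy shared across the package."""


class RetinaCommError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RetinaCommError):
    """Malformed input file: dimension mismatch, duplicate ids, bad columns."""


class ConfigurationError(RetinaCommError):
    """Invalid configuration: missing fields, genes absent from the universe."""


class MissingDataError(RetinaCommError):
    """A required group/timepoint has no scored observations."""


class UndefinedScoreError(RetinaCommError):
    """A score was requested for an empty cell group."""


class InsufficientOverlapError(RetinaCommError):
    """Two datasets share too few genes to compare."""


class PlacementError(RetinaCommError):
    """Synthetic dots could not be placed without overlap."""
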