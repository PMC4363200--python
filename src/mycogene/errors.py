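"""Exception hierarchy for mycogene."""


class MycogeneError(Exception):
    """Base class for all package errors."""


class FormatError(MycogeneError):
    """Malformed input file (message names the offending file/line)."""


class ConsistencyError(MycogeneError):
    """Input is well-formed but internally inconsistent."""


class BoundsError(MycogeneError):
    """Coordinates outside the sequence they refer to."""


class ConfigError(MycogeneError):
    """Invalid run configuration."""


class TrainingError(MycogeneError):
    """Model training could not proceed (e.g. empty training set)."""
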