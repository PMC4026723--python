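"""Exception hierarchy shared across the pipeline."""


class CpgDescentError(Exception):
    """Base class for all package errors."""


class TreeError(CpgDescentError):
    """Malformed or unusable phylogenetic tree."""


class CalibrationError(CpgDescentError):
    """Divergence-time calibration inconsistent with the branch model."""


class DataError(CpgDescentError):
    """Input records violate a format or content contract."""


class UsageError(CpgDescentError):
    """Caller combined operations or arguments incorrectly."""
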