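"""Exception hierarchy shared across the pipeline stages."""


class ChimeraError(Exception):
    """Base class for all package errors."""


class CigarError(ChimeraError):
    """Malformed or unsupported CIGAR string."""


class ReferenceLookupError(ChimeraError):
    """Unknown chromosome or unusable reference."""


class PairingError(ChimeraError):
    """Mate streams or mate records that do not pair up."""


class ConfigurationError(ChimeraError):
    """Invalid parameters or aligner configuration."""


class RealignmentError(ChimeraError):
    """External aligner failed or produced unreadable output."""


class JoinError(ChimeraError):
    """Realigned record whose name cannot be joined back to its origin."""


class SimulationError(ChimeraError):
    """Simulator could not place a planted feature."""
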