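"""Exception hierarchy for protocol, measurement, and pipeline failures."""


class DGEphysError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DGEphysError, ValueError):
    """A generator or measurement was called with out-of-domain parameters."""


class ProtocolError(DGEphysError):
    """A trace does not carry the epoch annotations a measurement requires."""


class ContaminatedProtocolError(ProtocolError):
    """A nominally subthreshold epoch contains an action potential.

    ``amplitude`` names the offending stimulus amplitude when known.
    """

    def __init__(self, message: str, amplitude: float | None = None):
        super().__init__(message)
        self.amplitude = amplitude


class InsufficientDataError(DGEphysError):
    """Too few amplitudes, values, or complete cases for the computation."""


class IntegrationError(DGEphysError):
    """The membrane-potential integration diverged."""


class InvalidSpecError(DGEphysError, ValueError):
    """A population specification is infeasible (e.g. negative variance)."""


class FormatError(DGEphysError):
    """A trace bundle on disk violates the container schema."""
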