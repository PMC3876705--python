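"""Exception hierarchy.

``NeopatchError`` is the common base so callers (and the CLI) can separate
configuration problems (exit code 2) from runtime failures (exit code 1).
"""


class NeopatchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeopatchError):
    """Invalid or incomplete run configuration (missing rule, bad schema)."""


class InvalidGeometryError(NeopatchError):
    """Non-positive compartment dimensions."""


class EmptyNetworkError(NeopatchError):
    """Patch too small to hold a single lattice site."""


class CalibrationError(NeopatchError):
    """Requested edge count unreachable even at probability 1."""


class PartitionError(NeopatchError):
    """Invalid partition request (e.g. more ranks than neurons)."""


class RoutingError(NeopatchError):
    """Spike emitted by a neuron with no partition assignment."""


class IntegrationError(NeopatchError):
    """Non-finite state encountered while stepping the membrane equations."""

    def __init__(self, message: str, neuron_id: int | None = None,
                 step: int | None = None):
        super().__init__(message)
        self.neuron_id = neuron_id
        self.step = step


class UndefinedFractionError(NeopatchError):
    """Barrier fraction requested for a record with zero total time."""
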