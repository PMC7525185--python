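"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`CirclinkError`
so callers (and the CLI) can catch library failures without masking bugs.
"""


class CirclinkError(Exception):
    """Base class for all circlink errors."""


class ParseError(CirclinkError):
    """A text input file could not be parsed; message names the line."""


class EmptyNetworkError(CirclinkError):
    """An edge-list file contained no usable edges."""


class ShapeError(CirclinkError):
    """A matrix had an incompatible or non-square shape."""


class RegistryError(CirclinkError, KeyError):
    """An identifier is not present in the relevant entity registry."""


class ZeroVarianceError(CirclinkError):
    """A vector handed to a correlation measure is constant."""


class BandwidthUndefinedError(CirclinkError):
    """All interaction profiles are zero; the GIP bandwidth is undefined."""


class UnknownTermError(CirclinkError, KeyError):
    """A disease term is absent from the semantic DAG."""


class DegenerateKernelError(CirclinkError):
    """A kernel row/column has no mass to normalize over."""


class ConfigurationError(CirclinkError):
    """An invalid or insufficient configuration was supplied."""


class NumericalFailureError(CirclinkError):
    """Non-finite values appeared during an iterative computation."""


class TrainingError(CirclinkError):
    """The classifier cannot be trained on the supplied dataset."""


class SamplingError(CirclinkError):
    """A negative sample of the requested size cannot be drawn."""
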