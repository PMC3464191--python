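"""Exception hierarchy.

Every error raised by the package derives from :class:`ChanCavError` so
callers can distinguish pipeline failures from programming errors.
"""


class ChanCavError(Exception):
    """Base class for all package errors."""


class FormatError(ChanCavError):
    """A structure/trajectory/grid file could not be parsed."""


class ClassificationError(ChanCavError):
    """An atom or residue could not be assigned a species class."""


class TopologyError(ChanCavError):
    """Topology and coordinates disagree (atom counts, chains, ...)."""


class SpecError(ChanCavError):
    """A synthetic-channel specification is internally inconsistent."""


class GeometryError(ChanCavError):
    """Degenerate geometry (collinear selections, <3 atoms, ...)."""


class AlignmentError(ChanCavError):
    """Pore-axis anchors missing or time bases that cannot be aligned."""


class SamplingError(ChanCavError):
    """Requested stride/window does not fit the trajectory."""


class SelectionError(ChanCavError):
    """An atom/species selection is empty."""


class PrecisionError(ChanCavError):
    """Too few samples/iterations for a meaningful estimate."""


class FitError(ChanCavError):
    """A model fit failed to converge or lacks data."""


class UnsupportedGridError(ChanCavError):
    """Grid layout not representable in the requested output format."""
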