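"""Exception hierarchy for mrhotspot."""


class MrHotspotError(Exception):
    """Base class for all package-specific errors."""


class GridMismatchError(MrHotspotError):
    """Two volumes do not share a compatible grid."""


class VolumeFormatError(MrHotspotError):
    """A file on disk is not a usable single 3D NIfTI volume."""


class DisjointExtentError(MrHotspotError):
    """Source and target grids do not overlap in physical space."""


class EmptyRegionError(MrHotspotError):
    """An operation requires a non-empty region (mask or defined domain)."""


class QualityMapMissingError(MrHotspotError):
    """A quality map required by a rejection rule is not available."""


class ConfigError(MrHotspotError):
    """Invalid pipeline configuration."""
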