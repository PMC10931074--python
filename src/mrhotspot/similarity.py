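"""Correspondence metrics: Sørensen–Dice overlap and center-of-intensity
distances (COIDs) between hotspot masks.

DSC = 2|A ∩ B| / (|A| + |B|) measures voxel-set overlap; the center of
intensity is the intensity-weighted mean of voxel-center positions, and the
COID is the Euclidean distance between two such centers, reported in cm.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import EmptyRegionError
from .volumes import BinaryMask, ScalarMap, _check_compatible

MM_PER_CM = 10.0


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Sørensen–Dice coefficient 2|a∩b| / (|a|+|b|) on compatible grids."""
    _check_compatible(a.grid, b.grid)
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        raise EmptyRegionError("DSC is undefined for two empty masks")
    inter = int((a.members & b.members).sum())
    return 2.0 * inter / (na + nb)


def center_of_intensity(smap: ScalarMap, mask: BinaryMask) -> np.ndarray:
    """Intensity-weighted mean voxel-center position over a mask, in cm.

    Weights are the raw map values (the formula is scale-invariant, so no
    normalization is needed).  Negative values — possible in noisy ratio
    fits — are clipped to 0 with a warning; a zero total intensity or any
    undefined voxel inside the mask is an error.
    """
    _check_compatible(smap.grid, mask.grid)
    if mask.is_empty:
        raise EmptyRegionError("center of intensity of an empty mask")
    if not smap.domain[mask.members].all():
        raise ValueError("map is undefined on part of the mask")
    weights = smap.values[mask.members]
    if (weights < 0).any():
        warnings.warn("negative intensities clipped to 0 for center-of-intensity weighting",
                      stacklevel=2)
        weights = np.clip(weights, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise ValueError("total intensity is zero; center of intensity undefined")
    idx = np.argwhere(mask.members).astype(float)
    pos_mm = idx * np.asarray(smap.grid.voxel_size) + np.asarray(smap.grid.origin)
    return (weights[:, None] * pos_mm).sum(axis=0) / total / MM_PER_CM


def coid(
    map_a: ScalarMap,
    hot_a: BinaryMask,
    map_b: ScalarMap,
    hot_b: BinaryMask,
) -> float:
    """Euclidean distance (cm) between two centers of intensity."""
    ca = center_of_intensity(map_a, hot_a)
    cb = center_of_intensity(map_b, hot_b)
    return float(np.linalg.norm(ca - cb))


@dataclasses.dataclass(frozen=True)
class SimilarityRecord:
    """One hotspot-pair comparison for one subject.

    ``comparator`` identifies the second member of the pair: "roi" for a
    hotspot-vs-full-segmentation overlap, or the name of the map ("t1",
    "t2") whose hotspot was compared.  ``coid_cm`` is NaN where a COID was
    not computed (e.g. hotspot-vs-segmentation rows).
    """

    map_name: str
    roi_name: str
    comparator: str
    dsc: float
    coid_cm: float
    n_a: int
    n_b: int
    n_overlap: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError(f"DSC out of [0, 1]: {self.dsc}")
        if np.isfinite(self.coid_cm) and self.coid_cm < 0:
            raise ValueError("COID must be non-negative")
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap cannot exceed either set size")
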