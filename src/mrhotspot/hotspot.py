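"""NAWM-referenced hotspot definition and threshold sweeps.

Within a segmentation, a hotspot is the set of defined voxels whose value
strictly exceeds ``factor`` times the median of the same map in the
normal-appearing white matter reference region (default factor 1.5, i.e.
150 % of the NAWM median).  A factor of 0 recovers the whole defined ROI,
which is useful for reporting un-thresholded region medians.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRegionError
from .volumes import BinaryMask, ScalarMap, _check_compatible


def nawm_reference_median(smap: ScalarMap, nawm: BinaryMask) -> float:
    """Median of the map over defined voxels of the NAWM reference region.

    Even-count convention: mean of the central pair.
    """
    vals = smap.values_in(nawm)
    if vals.size == 0:
        raise EmptyRegionError("no defined voxels of the map inside the NAWM region")
    return float(np.median(vals))


@dataclasses.dataclass
class HotspotResult:
    """A thresholded voxel set plus the reference that defined it."""

    mask: BinaryMask
    map_name: str
    roi_name: str
    nawm_median: float
    threshold_factor: float

    @property
    def is_empty(self) -> bool:
        return self.mask.is_empty

    @property
    def size(self) -> int:
        return self.mask.count


def define_hotspot(
    smap: ScalarMap,
    roi: BinaryMask,
    nawm_median: float,
    factor: float = 1.5,
    map_name: str = "",
    roi_name: str = "",
) -> HotspotResult:
    """Voxels of the ROI with value strictly greater than factor × NAWM median.

    Ties at exactly the threshold are excluded.  An empty hotspot is a
    valid result (flagged with a warning); downstream statistics treat it
    as a missing observation.
    """
    if not math.isfinite(nawm_median):
        raise ValueError("nawm_median must be finite")
    if factor < 0:
        raise ValueError("threshold factor must be >= 0")
    if roi.is_empty:
        raise EmptyRegionError("ROI is empty")
    _check_compatible(smap.grid, roi.grid)
    with np.errstate(invalid="ignore"):
        members = roi.members & smap.domain & (smap.values > factor * nawm_median)
    result = HotspotResult(
        BinaryMask(smap.grid, members), map_name, roi_name, float(nawm_median), float(factor)
    )
    if result.is_empty:
        warnings.warn(
            f"empty hotspot for map={map_name or '?'} roi={roi_name or '?'} "
            f"(factor {factor} x NAWM median {nawm_median:g})",
            stacklevel=2,
        )
    return result


def threshold_sweep(
    smap: ScalarMap,
    roi: BinaryMask,
    nawm_median: float,
    factors: Sequence[float],
) -> pd.DataFrame:
    """Hotspot size and median for each threshold factor.

    Factors must be sorted ascending.  Sizes are non-increasing and medians
    non-decreasing in the factor; the median of an empty hotspot is NaN.
    Returns a tidy frame with columns factor, size, median.
    """
    factors = list(factors)
    if any(b < a for a, b in zip(factors, factors[1:])):
        raise ValueError("factors must be sorted ascending")
    rows = []
    for f in factors:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hs = define_hotspot(smap, roi, nawm_median, f)
        vals = smap.values_in(hs.mask)
        rows.append(
            {"factor": f, "size": hs.size, "median": float(np.median(vals)) if vals.size else np.nan}
        )
    return pd.DataFrame(rows)
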