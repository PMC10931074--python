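"""Construction of the four-region system TU / TU+PT / PT / NAWM.

The tumor segmentation (TU) is dilated by a fixed number of face-connected
iterations (default 6, ~2 cm on a 3.4 mm grid) to obtain TU+PT; the
peritumoral shell PT is the set difference; the normal-appearing white
matter (NAWM) reference is the white-matter mask minus TU+PT, eroded once.
"""

from __future__ import annotations

import dataclasses

from scipy import ndimage

from .errors import EmptyRegionError
from .volumes import BinaryMask, _check_compatible


def _structure(connectivity: int):
    if connectivity not in (1, 2, 3):
        raise ValueError("connectivity must be 1 (face), 2 (edge) or 3 (vertex)")
    return ndimage.generate_binary_structure(3, connectivity)


def dilate(mask: BinaryMask, n: int, connectivity: int = 1) -> BinaryMask:
    """Morphological dilation by ``n`` single-voxel iterations.

    Face-connected (6-neighbour) by default; dilation is clipped at the
    grid boundary (no wraparound).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mask.is_empty:
        raise EmptyRegionError("cannot dilate an empty mask")
    out = ndimage.binary_dilation(mask.members, structure=_structure(connectivity), iterations=n)
    return BinaryMask(mask.grid, out)


def erode(mask: BinaryMask, n: int, connectivity: int = 1) -> BinaryMask:
    """Morphological erosion by ``n`` iterations (dual of :func:`dilate`).

    Outside the grid counts as foreground, making erosion the exact dual of
    boundary-clipped dilation (so closing contains the original even at the
    grid edge).  The result may be empty.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = ndimage.binary_erosion(
        mask.members, structure=_structure(connectivity), iterations=n, border_value=1
    )
    return BinaryMask(mask.grid, out)


@dataclasses.dataclass
class RoiSet:
    """The four analysis regions.

    Invariants (checked on construction): tu ⊆ tu_pt; pt = tu_pt \\ tu;
    pt ∩ tu = ∅; nawm ∩ tu_pt = ∅.
    """

    tu: BinaryMask
    tu_pt: BinaryMask
    pt: BinaryMask
    nawm: BinaryMask

    def __post_init__(self) -> None:
        _check_compatible(self.tu.grid, self.tu_pt.grid)
        _check_compatible(self.tu.grid, self.pt.grid)
        _check_compatible(self.tu.grid, self.nawm.grid)
        if not self.tu.issubset(self.tu_pt):
            raise ValueError("RoiSet invariant violated: tu must be a subset of tu_pt")
        if (self.pt.members != (self.tu_pt.members & ~self.tu.members)).any():
            raise ValueError("RoiSet invariant violated: pt must equal tu_pt \\ tu")
        if (self.nawm.members & self.tu_pt.members).any():
            raise ValueError("RoiSet invariant violated: nawm must be disjoint from tu_pt")

    def region(self, name: str) -> BinaryMask:
        """Look up a region by its conventional name."""
        key = name.lower().replace("+", "_").replace(" ", "")
        try:
            return {"tu": self.tu, "tu_pt": self.tu_pt, "pt": self.pt, "nawm": self.nawm}[key]
        except KeyError:
            raise KeyError(f"unknown region {name!r}; expected TU, TU+PT, PT or NAWM") from None


def build_roi_set(
    tu: BinaryMask,
    wm: BinaryMask,
    dilation_voxels: int = 6,
    connectivity: int = 1,
    nawm_erosion: int = 1,
) -> RoiSet:
    """Derive TU+PT, PT and NAWM from the tumor segmentation and a WM mask.

    Raises
    ------
    EmptyRegionError
        If TU is empty, or the derived NAWM reference region is empty
        (an unusable reference).
    """
    _check_compatible(tu.grid, wm.grid)
    if tu.is_empty:
        raise EmptyRegionError("tumor segmentation is empty")
    if dilation_voxels < 0:
        raise ValueError("dilation_voxels must be >= 0")
    tu_pt = dilate(tu, dilation_voxels, connectivity) if dilation_voxels > 0 else BinaryMask(
        tu.grid, tu.members.copy()
    )
    pt = tu_pt.difference(tu)
    nawm = wm.difference(tu_pt)
    if nawm_erosion > 0 and not nawm.is_empty:
        nawm = erode(nawm, nawm_erosion, connectivity)
    if nawm.is_empty:
        raise EmptyRegionError("NAWM reference region is empty after subtraction and erosion")
    return RoiSet(tu=tu, tu_pt=tu_pt, pt=pt, nawm=nawm)
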