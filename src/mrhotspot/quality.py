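"""MRSI voxel-level quality control and ratio-map computation.

A spectroscopy voxel enters the analysis only if the total-creatine
linewidth (FWHM), total-creatine SNR, the metabolite's Cramér–Rao lower
bound (CRLB) and a robust outlier filter on the fit coefficient all pass.
Rejected voxels become undefined in the metabolite's maps, and undefinedness
propagates into every ratio built from that metabolite.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .errors import EmptyRegionError, QualityMapMissingError
from .roi import RoiSet
from .volumes import BinaryMask, ScalarMap, _check_compatible


@dataclasses.dataclass(frozen=True)
class QualityRule:
    """Voxel rejection thresholds.

    Defaults: FWHM > 0.15 ppm, SNR < 5, CRLB > 80 %, or fit coefficient
    more than 13 median absolute deviations from the map median.  Broad
    lines indicate poor spectral quality, so high FWHM is discarded by
    default; set ``discard_high_fwhm=False`` to invert the direction.
    """

    fwhm_max: float = 0.15
    snr_min: float = 5.0
    crlb_max: float = 80.0
    mad_k: float = 13.0
    discard_high_fwhm: bool = True

    def __post_init__(self) -> None:
        for name in ("fwhm_max", "snr_min", "crlb_max", "mad_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclasses.dataclass
class QualityMaps:
    """Per-subject quality volumes on the MRSI grid.

    ``crlb`` and ``fit_coeff`` are keyed by metabolite name (e.g. "gln",
    "tnaa").
    """

    fwhm_tcr: ScalarMap
    snr_tcr: ScalarMap
    crlb: dict[str, ScalarMap]
    fit_coeff: dict[str, ScalarMap]

    def __post_init__(self) -> None:
        grid = self.fwhm_tcr.grid
        _check_compatible(grid, self.snr_tcr.grid)
        for m in list(self.crlb.values()) + list(self.fit_coeff.values()):
            _check_compatible(grid, m.grid)


def mad_outlier_mask(smap: ScalarMap, k: float) -> BinaryMask:
    """Mask of voxels rejected by the MAD outlier rule.

    A defined voxel is rejected when |value − median| > k · MAD, with
    MAD = median(|value − median|) over the whole defined domain.  A
    degenerate MAD of zero (e.g. a constant map) rejects nothing rather
    than annihilating every off-median voxel.
    """
    vals = smap.defined_values()
    if vals.size == 0:
        raise EmptyRegionError("MAD filter requires at least one defined voxel")
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0:
        return BinaryMask(smap.grid, np.zeros(smap.grid.shape, dtype=bool))
    with np.errstate(invalid="ignore"):
        rejected = smap.domain & (np.abs(smap.values - med) > k * mad)
    return BinaryMask(smap.grid, rejected)


def apply_quality_rule(metabolite: str, quality: QualityMaps, rule: QualityRule) -> BinaryMask:
    """Accepted-voxel mask for one metabolite under the full rule conjunction.

    A voxel is accepted iff it is defined in every relevant quality map and
    passes the FWHM, SNR, CRLB and MAD criteria.
    """
    if metabolite not in quality.crlb:
        raise QualityMapMissingError(f"no CRLB map for metabolite {metabolite!r}")
    if metabolite not in quality.fit_coeff:
        raise QualityMapMissingError(f"no fit-coefficient map for metabolite {metabolite!r}")
    fwhm, snr = quality.fwhm_tcr, quality.snr_tcr
    crlb = quality.crlb[metabolite]
    fit = quality.fit_coeff[metabolite]
    defined = fwhm.domain & snr.domain & crlb.domain & fit.domain
    with np.errstate(invalid="ignore"):
        if rule.discard_high_fwhm:
            fwhm_ok = fwhm.values <= rule.fwhm_max
        else:
            fwhm_ok = fwhm.values >= rule.fwhm_max
        snr_ok = snr.values >= rule.snr_min
        crlb_ok = crlb.values <= rule.crlb_max
    mad_rejected = mad_outlier_mask(fit, rule.mad_k).members
    accepted = defined & fwhm_ok & snr_ok & crlb_ok & ~mad_rejected
    return BinaryMask(fwhm.grid, accepted)


def ratio_map(
    numerator: ScalarMap,
    denominator: ScalarMap,
    accepted_num: BinaryMask | None = None,
    accepted_den: BinaryMask | None = None,
) -> ScalarMap:
    """num/den wherever both maps are defined, accepted, and den > 0.

    Degenerate voxels (zero or negative denominator, any rejection) become
    undefined rather than raising.
    """
    _check_compatible(numerator.grid, denominator.grid)
    ok = numerator.domain & denominator.domain
    if accepted_num is not None:
        _check_compatible(numerator.grid, accepted_num.grid)
        ok &= accepted_num.members
    if accepted_den is not None:
        _check_compatible(numerator.grid, accepted_den.grid)
        ok &= accepted_den.members
    with np.errstate(invalid="ignore"):
        ok &= denominator.values > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(ok, numerator.values / denominator.values, np.nan)
    return ScalarMap(numerator.grid, vals, "ratio", ok)


def mask_map(smap: ScalarMap, accepted: BinaryMask) -> ScalarMap:
    """Restrict a map's defined domain to an accepted-voxel mask."""
    _check_compatible(smap.grid, accepted.grid)
    domain = smap.domain & accepted.members
    return ScalarMap(smap.grid, np.where(domain, smap.values, np.nan), smap.unit, domain)


@dataclasses.dataclass(frozen=True)
class UsabilityReport:
    """Outcome of the subject-level usability check."""

    passed: bool
    max_undefined_fraction: float
    undefined_fractions: dict[str, float]

    @property
    def worst(self) -> float:
        return max(self.undefined_fractions.values()) if self.undefined_fractions else 0.0


def subject_usability_check(
    ratio_maps: Mapping[str, ScalarMap],
    roi: RoiSet,
    max_undefined_fraction: float = 0.5,
) -> UsabilityReport:
    """Flag subjects whose excluded-voxel burden precludes analysis.

    Fails when the undefined fraction inside TU+PT exceeds the threshold
    for any analyzed map.
    """
    fractions: dict[str, float] = {}
    region = roi.tu_pt.members
    n = int(region.sum())
    for name, smap in ratio_maps.items():
        _check_compatible(smap.grid, roi.tu_pt.grid)
        defined = int((smap.domain & region).sum())
        fractions[name] = 1.0 - defined / n if n else 0.0
    passed = all(f <= max_undefined_fraction for f in fractions.values())
    return UsabilityReport(passed, max_undefined_fraction, fractions)
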