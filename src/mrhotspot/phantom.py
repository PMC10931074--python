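"""Synthetic multi-subject phantom datasets with known ground truth.

Each phantom subject is a digital brain: an ellipsoidal brain volume whose
interior white matter carries normal-appearing levels, an ellipsoidal tumor,
and a peritumoral shell (the face-connected dilation of the tumor minus the
tumor itself).  Every analyzed map (T1, T2, eight metabolite ratios) is
painted region-wise at configurable levels — the defaults are
glioma-cohort medians for tumor / peritumoral / NAWM tissue — and degraded
with multiplicative Gaussian noise.  Quality volumes (tCr FWHM and SNR,
per-metabolite CRLB and fit coefficient) are emitted with a configurable
fraction of voxels planted to violate each rejection rule, and the planted
sets are recorded so the quality filter can be checked exactly.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Sequence

import numpy as np

from .roi import build_roi_set, dilate
from .volumes import BinaryMask, Grid, ScalarMap
from .quality import QualityMaps

MRSI_MAPS = (
    "tcho_tnaa", "gln_tnaa", "gly_tnaa", "ins_tnaa",
    "tcho_tcr", "gln_tcr", "gly_tcr", "ins_tcr",
)
MRF_MAPS = ("t1", "t2")
ALL_MAPS = MRF_MAPS + MRSI_MAPS

MAP_DISPLAY = {
    "t1": "T1", "t2": "T2",
    "tcho_tnaa": "tCho/tNAA", "gln_tnaa": "Gln/tNAA",
    "gly_tnaa": "Gly/tNAA", "ins_tnaa": "Ins/tNAA",
    "tcho_tcr": "tCho/tCr", "gln_tcr": "Gln/tCr",
    "gly_tcr": "Gly/tCr", "ins_tcr": "Ins/tCr",
}
MAP_UNIT = {m: ("ms" if m in MRF_MAPS else "ratio") for m in ALL_MAPS}

METABOLITES = ("tcho", "gln", "gly", "ins", "tnaa", "tcr")
RATIO_COMPONENTS = {
    "tcho_tnaa": ("tcho", "tnaa"), "gln_tnaa": ("gln", "tnaa"),
    "gly_tnaa": ("gly", "tnaa"), "ins_tnaa": ("ins", "tnaa"),
    "tcho_tcr": ("tcho", "tcr"), "gln_tcr": ("gln", "tcr"),
    "gly_tcr": ("gly", "tcr"), "ins_tcr": ("ins", "tcr"),
}


@dataclasses.dataclass(frozen=True)
class RegionLevels:
    """Planted map level per tissue region (map units)."""

    tumor: float
    peritumoral: float
    nawm: float

    def __post_init__(self) -> None:
        if min(self.tumor, self.peritumoral, self.nawm) <= 0:
            raise ValueError("region levels must be positive")


#: Default region levels: cohort medians in tumor / peritumoral / NAWM tissue
#: for each analyzed quantity (T1 and T2 in ms, ratios unitless).
DEFAULT_LEVELS: dict[str, RegionLevels] = {
    "t1": RegionLevels(1724.0, 1756.0, 950.0),
    "t2": RegionLevels(85.5, 102.0, 42.9),
    "tcho_tnaa": RegionLevels(0.48, 0.38, 0.20),
    "gln_tnaa": RegionLevels(0.61, 0.38, 0.16),
    "gly_tnaa": RegionLevels(0.28, 0.20, 0.07),
    "ins_tnaa": RegionLevels(1.15, 1.06, 0.54),
    "tcho_tcr": RegionLevels(0.69, 0.76, 0.37),
    "gln_tcr": RegionLevels(0.90, 0.67, 0.32),
    "gly_tcr": RegionLevels(0.51, 0.42, 0.15),
    "ins_tcr": RegionLevels(1.98, 1.97, 1.05),
}

#: Default planted fractions of brain voxels violating each quality rule.
DEFAULT_DEFECT_FRACTIONS: dict[str, float] = {"fwhm": 0.02, "snr": 0.02, "crlb": 0.02, "fit": 0.01}

# nominal (pre-defect) quality values, all comfortably inside the accepted range
_GOOD_FWHM_PPM = 0.06
_GOOD_SNR = 20.0
_GOOD_CRLB_PCT = 10.0
_BAD_FWHM_PPM = 0.30
_BAD_SNR = 2.0
_BAD_CRLB_PCT = 100.0
_BAD_FIT_OFFSET = 1000.0


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, levels, noise and defect model for one phantom subject.

    The default grid is the whole-brain MRSI matrix (64 × 64 × 39 voxels at
    3.4 mm isotropic); tests use smaller grids for speed.  Levels are per
    map; noise is a multiplicative Gaussian coefficient of variation.
    """

    shape: tuple[int, int, int] = (64, 64, 39)
    voxel_size: tuple[float, float, float] = (3.4, 3.4, 3.4)
    brain_semiaxes_mm: tuple[float, float, float] | None = None
    wm_shrink_voxels: int = 2
    tumor_center_offset_mm: tuple[float, float, float] | None = None
    tumor_semiaxes_mm: tuple[float, float, float] | None = None
    levels: dict[str, RegionLevels] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LEVELS)
    )
    noise_cv: float = 0.1
    defect_fractions: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DEFECT_FRACTIONS)
    )
    dilation_voxels: int = 6
    connectivity: int = 1
    infiltration_gradient: bool = False

    def __post_init__(self) -> None:
        if self.brain_semiaxes_mm is None:
            # fill ~88% of the field of view so the brain clears the edges
            ext = [s * v / 2 for s, v in zip(self.shape, self.voxel_size)]
            self.brain_semiaxes_mm = tuple(0.88 * e for e in ext)
        bx, by, bz = self.brain_semiaxes_mm
        if self.tumor_semiaxes_mm is None:
            # a glioma-scale lesion (~2 cm semi-axes on the whole-brain grid),
            # shrunk proportionally on smaller test grids
            self.tumor_semiaxes_mm = (min(20.0, 0.22 * bx), min(18.0, 0.20 * by),
                                      min(14.0, 0.24 * bz))
        if self.tumor_center_offset_mm is None:
            # lateral lesion, clear of the brain edge even after dilation
            self.tumor_center_offset_mm = (min(25.0, 0.35 * bx), 0.0, 0.0)
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name, frac in self.defect_fractions.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"defect fraction {name} must be in [0, 1]")

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.voxel_size)


@dataclasses.dataclass
class PhantomGeometry:
    """Deterministic region masks derived from a PhantomSpec."""

    grid: Grid
    brain: BinaryMask
    wm: BinaryMask
    tumor: BinaryMask
    pt_shell: BinaryMask  # dilation shell clipped to the brain
    normal: BinaryMask    # brain voxels outside tumor and shell


def _ellipsoid(grid: Grid, center_mm: np.ndarray, semiaxes_mm: Sequence[float]) -> np.ndarray:
    centers = grid.voxel_centers_mm()
    rel = (centers - center_mm) / np.asarray(semiaxes_mm, dtype=float)
    return (rel**2).sum(axis=-1) <= 1.0


def build_geometry(spec: PhantomSpec) -> PhantomGeometry:
    """Region masks for a phantom subject (no randomness)."""
    grid = spec.grid
    fov_center = (np.asarray(grid.shape) - 1) / 2 * np.asarray(grid.voxel_size)
    brain_arr = _ellipsoid(grid, fov_center, spec.brain_semiaxes_mm)
    brain = BinaryMask(grid, brain_arr)
    if spec.wm_shrink_voxels > 0:
        from .roi import erode

        wm = erode(brain, spec.wm_shrink_voxels, spec.connectivity)
    else:
        wm = BinaryMask(grid, brain_arr.copy())
    tumor_center = fov_center + np.asarray(spec.tumor_center_offset_mm)
    tumor_arr = _ellipsoid(grid, tumor_center, spec.tumor_semiaxes_mm)
    if not tumor_arr.any():
        raise ValueError("tumor ellipsoid contains no voxels on this grid")
    if (tumor_arr & ~brain_arr).any():
        raise ValueError("tumor extends outside the brain")
    tumor = BinaryMask(grid, tumor_arr)
    dilated = dilate(tumor, spec.dilation_voxels, spec.connectivity) if spec.dilation_voxels else tumor
    pt_shell = BinaryMask(grid, dilated.members & ~tumor_arr & brain_arr)
    normal = BinaryMask(grid, brain_arr & ~dilated.members)
    return PhantomGeometry(grid, brain, wm, tumor, pt_shell, normal)


@dataclasses.dataclass
class SubjectDataset:
    """The volumes one phantom subject contributes to the analysis."""

    subject_id: str
    grid: Grid
    maps: dict[str, ScalarMap]
    tu: BinaryMask
    wm: BinaryMask
    quality: QualityMaps


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    region_masks: dict[str, BinaryMask]          # tumor / peritumoral / normal / brain
    planted_levels: dict[str, RegionLevels]      # after any between-subject jitter
    rejected_fwhm: BinaryMask
    rejected_snr: BinaryMask
    rejected_crlb: dict[str, BinaryMask]
    rejected_fit: dict[str, BinaryMask]


def _paint_levels(geom: PhantomGeometry, levels: RegionLevels, spec: PhantomSpec) -> np.ndarray:
    base = np.full(geom.grid.shape, np.nan)
    base[geom.normal.members] = levels.nawm
    if spec.infiltration_gradient and spec.dilation_voxels > 0:
        # linear decay from tumor level at the inner edge of the shell to the
        # NAWM level at its outer edge, by face-connected dilation step
        from scipy import ndimage

        steps = np.full(geom.grid.shape, np.inf)
        cur = geom.tumor.members.copy()
        struct = ndimage.generate_binary_structure(3, spec.connectivity)
        for k in range(1, spec.dilation_voxels + 1):
            nxt = ndimage.binary_dilation(cur, structure=struct)
            ring = nxt & ~cur & geom.pt_shell.members
            steps[ring] = k
            cur = nxt
        frac = (steps - 1) / max(spec.dilation_voxels - 1, 1)
        shell = geom.pt_shell.members
        base[shell] = levels.tumor + (levels.nawm - levels.tumor) * frac[shell]
    else:
        base[geom.pt_shell.members] = levels.peritumoral
    base[geom.tumor.members] = levels.tumor
    return base


def _noisy(base: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return base.copy()
    noise = 1.0 + cv * rng.standard_normal(base.shape)
    return np.clip(base * noise, 0.0, None)


def _plant(
    rng: np.random.Generator, candidates: np.ndarray, fraction: float
) -> np.ndarray:
    """Boolean array marking a random ``fraction`` of candidate voxels."""
    out = np.zeros(candidates.shape, dtype=bool)
    idx = np.flatnonzero(candidates)
    k = int(round(fraction * idx.size))
    if k:
        chosen = rng.choice(idx, size=k, replace=False)
        out.flat[chosen] = True
    return out


def _make_quality(
    geom: PhantomGeometry, spec: PhantomSpec, rng: np.random.Generator
) -> tuple[QualityMaps, dict]:
    grid, brain = geom.grid, geom.brain.members
    fracs = spec.defect_fractions

    def brain_map(values: np.ndarray, unit: str) -> ScalarMap:
        arr = np.where(brain, values, np.nan)
        return ScalarMap(grid, arr, unit)

    fwhm_bad = _plant(rng, brain, fracs.get("fwhm", 0.0))
    snr_bad = _plant(rng, brain, fracs.get("snr", 0.0))
    fwhm_vals = np.full(grid.shape, _GOOD_FWHM_PPM) + 0.005 * rng.standard_normal(grid.shape)
    fwhm_vals = np.clip(fwhm_vals, 0.01, None)
    fwhm_vals[fwhm_bad] = _BAD_FWHM_PPM
    snr_vals = np.clip(_GOOD_SNR + rng.standard_normal(grid.shape), 0.0, None)
    snr_vals[snr_bad] = _BAD_SNR

    crlb_maps: dict[str, ScalarMap] = {}
    fit_maps: dict[str, ScalarMap] = {}
    crlb_bad: dict[str, BinaryMask] = {}
    fit_bad: dict[str, BinaryMask] = {}
    for met in METABOLITES:
        cb = _plant(rng, brain, fracs.get("crlb", 0.0))
        fb = _plant(rng, brain, fracs.get("fit", 0.0))
        crlb_vals = np.clip(_GOOD_CRLB_PCT + 2.0 * rng.standard_normal(grid.shape), 0.0, None)
        crlb_vals[cb] = _BAD_CRLB_PCT
        fit_vals = rng.standard_normal(grid.shape)
        fit_vals[fb] = _BAD_FIT_OFFSET
        crlb_maps[met] = brain_map(crlb_vals, "unitless")
        fit_maps[met] = brain_map(fit_vals, "unitless")
        crlb_bad[met] = BinaryMask(grid, cb)
        fit_bad[met] = BinaryMask(grid, fb)

    quality = QualityMaps(
        fwhm_tcr=brain_map(fwhm_vals, "ppm"),
        snr_tcr=brain_map(snr_vals, "unitless"),
        crlb=crlb_maps,
        fit_coeff=fit_maps,
    )
    planted = {
        "fwhm": BinaryMask(grid, fwhm_bad),
        "snr": BinaryMask(grid, snr_bad),
        "crlb": crlb_bad,
        "fit": fit_bad,
    }
    return quality, planted


def generate_subject(
    spec: PhantomSpec,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sub-01",
) -> tuple[SubjectDataset, GroundTruth]:
    """Generate one phantom subject.

    Map values are region level × (1 + cv·N(0,1)), truncated at zero, and
    defined only inside the brain.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    geom = build_geometry(spec)
    maps: dict[str, ScalarMap] = {}
    for name in sorted(spec.levels):
        base = _paint_levels(geom, spec.levels[name], spec)
        vals = _noisy(base, spec.noise_cv, rng)
        maps[name] = ScalarMap(geom.grid, vals, MAP_UNIT.get(name, "unitless"))
    quality, planted = _make_quality(geom, spec, rng)
    dataset = SubjectDataset(
        subject_id=subject_id,
        grid=geom.grid,
        maps=maps,
        tu=geom.tumor,
        wm=geom.wm,
        quality=quality,
    )
    truth = GroundTruth(
        region_masks={
            "tumor": geom.tumor,
            "peritumoral": geom.pt_shell,
            "normal": geom.normal,
            "brain": geom.brain,
        },
        planted_levels=dict(spec.levels),
        rejected_fwhm=planted["fwhm"],
        rejected_snr=planted["snr"],
        rejected_crlb=planted["crlb"],
        rejected_fit=planted["fit"],
    )
    return dataset, truth


def _jitter_levels(
    levels: dict[str, RegionLevels],
    rng: np.random.Generator,
    sd_abs: float | dict[str, float] = 0.0,
    sd_rel: float = 0.0,
) -> dict[str, RegionLevels]:
    out: dict[str, RegionLevels] = {}
    for name, lv in levels.items():
        sd = sd_abs.get(name, 0.0) if isinstance(sd_abs, dict) else sd_abs
        new = []
        for v in (lv.tumor, lv.peritumoral, lv.nawm):
            delta = sd * rng.standard_normal() + sd_rel * v * rng.standard_normal()
            new.append(max(v + delta, 1e-6))
        out[name] = RegionLevels(*new)
    return out


def generate_cohort(
    spec: PhantomSpec,
    n_subjects: int = 12,
    master_seed: int = 0,
    level_jitter_sd: float | dict[str, float] = 0.0,
    level_jitter_rel: float = 0.0,
) -> list[tuple[SubjectDataset, GroundTruth]]:
    """Generate a cohort of phantom subjects with derived per-subject seeds.

    Between-subject variation is modeled as Gaussian jitter of the planted
    region levels: ``level_jitter_sd`` is an absolute sd in map units
    (scalar or per-map dict), ``level_jitter_rel`` a relative sd applied to
    each level.  Jitter draws are independent per subject, map and region.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    jitter_ss, *subject_ss = ss.spawn(n_subjects + 1)
    jitter_rng = np.random.default_rng(jitter_ss)
    cohort = []
    for i, child in enumerate(subject_ss):
        sub_spec = spec
        if (isinstance(level_jitter_sd, dict) and level_jitter_sd) or (
            not isinstance(level_jitter_sd, dict) and level_jitter_sd > 0
        ) or level_jitter_rel > 0:
            sub_spec = copy.deepcopy(spec)
            sub_spec.levels = _jitter_levels(
                spec.levels, jitter_rng, level_jitter_sd, level_jitter_rel
            )
        cohort.append(generate_subject(sub_spec, child, subject_id=f"sub-{i + 1:02d}"))
    return cohort


# --------------------------------------------------------------------------
# Fast Monte-Carlo harness for statistical calibration
# --------------------------------------------------------------------------

def simulate_tu_pt_hotspot_medians(
    spec: PhantomSpec,
    map_name: str,
    n_cohorts: int,
    n_subjects: int = 12,
    seed: int = 0,
    threshold_factor: float = 1.5,
    level_jitter_sd: float = 0.0,
) -> np.ndarray:
    """Hotspot medians in TU and PT for many simulated cohorts.

    Generates single-map phantom volumes with shared geometry (computed
    once) and runs the real NAWM-reference / hotspot / summary code on each
    subject.  Returns an array of shape (n_cohorts, n_subjects, 2) holding
    the TU and PT hotspot medians; NaN marks an empty hotspot.
    """
    import warnings

    from .hotspot import define_hotspot, nawm_reference_median
    from .stats import region_summary

    geom = build_geometry(spec)
    roi = build_roi_set(geom.tumor, geom.wm, spec.dilation_voxels, spec.connectivity)
    levels = spec.levels[map_name]
    unit = MAP_UNIT.get(map_name, "unitless")
    rng = np.random.default_rng(seed)
    out = np.full((n_cohorts, n_subjects, 2), np.nan)
    for c in range(n_cohorts):
        for s in range(n_subjects):
            lv = RegionLevels(
                max(levels.tumor + level_jitter_sd * rng.standard_normal(), 1e-6),
                max(levels.peritumoral + level_jitter_sd * rng.standard_normal(), 1e-6),
                max(levels.nawm + level_jitter_sd * rng.standard_normal(), 1e-6),
            ) if level_jitter_sd > 0 else levels
            base = _paint_levels(geom, lv, spec)
            smap = ScalarMap(geom.grid, _noisy(base, spec.noise_cv, rng), unit)
            ref = nawm_reference_median(smap, roi.nawm)
            for j, region in enumerate((roi.tu, roi.pt)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hs = define_hotspot(smap, region, ref, threshold_factor)
                if not hs.is_empty:
                    out[c, s, j] = region_summary(smap, hs.mask)[0]
    return out
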