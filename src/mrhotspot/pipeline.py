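"""End-to-end analysis: quality filter → ROI build → NAWM medians →
hotspots → similarity metrics → cohort statistics.

The pipeline consumes a directory of per-subject NIfTI volumes (metabolite
ratio maps, T1/T2 maps, tumor and white-matter masks, optional quality
volumes), runs every stage on one analysis grid (the MRSI grid; MRF maps
are resampled linearly, masks with nearest-neighbour), and writes tidy TSV
tables plus rendered cohort reports.  It is deterministic given inputs and
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import yaml

from .errors import ConfigError, EmptyRegionError
from .hotspot import define_hotspot, nawm_reference_median
from .phantom import ALL_MAPS, MAP_UNIT, MRF_MAPS, MRSI_MAPS, RATIO_COMPONENTS, SubjectDataset
from .quality import (
    QualityMaps,
    QualityRule,
    apply_quality_rule,
    mask_map,
    subject_usability_check,
)
from .roi import RoiSet, build_roi_set
from .similarity import SimilarityRecord, coid, dice
from .stats import (
    CohortTable,
    SubjectSummary,
    build_report,
    region_summary,
    similarity_tidy_frame,
    subject_tidy_frame,
)
from .volumes import (
    BinaryMask,
    ScalarMap,
    read_mask,
    read_volume,
    resample_mask_to_grid,
    resample_to_grid,
    write_mask,
    write_volume,
)

log = logging.getLogger("mrhotspot")

HOTSPOT_REGIONS = ("tu", "tu_pt", "pt")


@dataclasses.dataclass
class PipelineConfig:
    """Declarative description of one analysis run."""

    input_dir: Path
    output_dir: Path
    maps: tuple[str, ...] = ALL_MAPS
    mrf_maps: tuple[str, ...] = MRF_MAPS
    threshold_factor: float = 1.5
    dilation_voxels: int = 6
    connectivity: int = 1
    nawm_erosion: int = 1
    quality_rule: QualityRule = dataclasses.field(default_factory=QualityRule)
    apply_quality: bool = True
    max_undefined_fraction: float = 0.5
    save_hotspots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        self.maps = tuple(self.maps)
        unknown = [m for m in self.maps if m not in ALL_MAPS]
        if unknown:
            raise ConfigError(f"unknown map name(s): {unknown}; expected among {ALL_MAPS}")
        if self.threshold_factor < 0:
            raise ConfigError("threshold_factor must be >= 0")
        if self.dilation_voxels < 0:
            raise ConfigError("dilation_voxels must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_dir"] = str(self.input_dir)
        d["output_dir"] = str(self.output_dir)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rule = raw.pop("quality_rule", None)
        raw.update(overrides)
        if rule is not None and "quality_rule" not in overrides:
            raw["quality_rule"] = QualityRule(**rule)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc


# --------------------------------------------------------------------------
# Subject dataset I/O (the directory layout the simulator writes)
# --------------------------------------------------------------------------

def write_subject_dataset(ds: SubjectDataset, out_dir: str | Path) -> Path:
    """Write one subject's volumes as NIfTI under ``out_dir/<subject_id>/``."""
    sub_dir = Path(out_dir) / ds.subject_id
    (sub_dir / "quality").mkdir(parents=True, exist_ok=True)
    for name, smap in ds.maps.items():
        write_volume(smap, sub_dir / f"{name}.nii.gz")
    write_mask(ds.tu, sub_dir / "tu.nii.gz")
    write_mask(ds.wm, sub_dir / "wm.nii.gz")
    q = ds.quality
    write_volume(q.fwhm_tcr, sub_dir / "quality" / "tcr_fwhm.nii.gz")
    write_volume(q.snr_tcr, sub_dir / "quality" / "tcr_snr.nii.gz")
    for met, m in q.crlb.items():
        write_volume(m, sub_dir / "quality" / f"{met}_crlb.nii.gz")
    for met, m in q.fit_coeff.items():
        write_volume(m, sub_dir / "quality" / f"{met}_fit.nii.gz")
    return sub_dir


def read_subject_dataset(sub_dir: str | Path, maps: tuple[str, ...] = ALL_MAPS) -> SubjectDataset:
    """Read a subject directory written by :func:`write_subject_dataset`."""
    sub_dir = Path(sub_dir)
    loaded: dict[str, ScalarMap] = {}
    for name in maps:
        path = sub_dir / f"{name}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing required volume {path}")
        loaded[name] = read_volume(path, MAP_UNIT[name])
    tu = read_mask(sub_dir / "tu.nii.gz")
    wm = read_mask(sub_dir / "wm.nii.gz")
    qdir = sub_dir / "quality"
    quality = None
    if (qdir / "tcr_fwhm.nii.gz").exists():
        crlb, fit = {}, {}
        for p in sorted(qdir.glob("*_crlb.nii.gz")):
            crlb[p.name.replace("_crlb.nii.gz", "")] = read_volume(p, "unitless")
        for p in sorted(qdir.glob("*_fit.nii.gz")):
            fit[p.name.replace("_fit.nii.gz", "")] = read_volume(p, "unitless")
        quality = QualityMaps(
            fwhm_tcr=read_volume(qdir / "tcr_fwhm.nii.gz", "ppm"),
            snr_tcr=read_volume(qdir / "tcr_snr.nii.gz", "unitless"),
            crlb=crlb,
            fit_coeff=fit,
        )
    return SubjectDataset(
        subject_id=sub_dir.name, grid=loaded[maps[0]].grid, maps=loaded, tu=tu, wm=wm,
        quality=quality,
    )


# --------------------------------------------------------------------------
# Per-subject analysis
# --------------------------------------------------------------------------

def _filtered_maps(ds: SubjectDataset, config: PipelineConfig) -> dict[str, ScalarMap]:
    """Quality-filter the ratio maps; T1/T2 pass through unfiltered."""
    out: dict[str, ScalarMap] = {}
    accepted_cache: dict[str, BinaryMask] = {}
    for name in config.maps:
        smap = ds.maps[name]
        if (
            config.apply_quality
            and ds.quality is not None
            and name in RATIO_COMPONENTS
        ):
            num, den = RATIO_COMPONENTS[name]
            for met in (num, den):
                if met not in accepted_cache:
                    accepted_cache[met] = apply_quality_rule(met, ds.quality, config.quality_rule)
            accepted = accepted_cache[num].intersection(accepted_cache[den])
            smap = mask_map(smap, accepted)
        out[name] = smap
    return out


def analyze_subject(
    ds: SubjectDataset, config: PipelineConfig
) -> tuple[SubjectSummary, RoiSet, dict[str, dict[str, BinaryMask]]]:
    """Run all stages for one subject.

    Returns the subject summary, the ROI set, and the hotspot masks keyed
    by map then region (for optional export).
    """
    # the analysis grid is the (coarser) MRSI grid when ratio maps are present
    mrsi_names = [n for n in config.maps if n in MRSI_MAPS]
    grid = ds.maps[mrsi_names[0]].grid if mrsi_names else ds.maps[config.maps[0]].grid
    # ensure everything lives on the analysis grid
    maps: dict[str, ScalarMap] = {}
    for name in config.maps:
        smap = ds.maps[name]
        if not smap.grid.is_compatible(grid):
            smap = resample_to_grid(smap, grid, method="linear")
        maps[name] = smap
    tu = ds.tu if ds.tu.grid.is_compatible(grid) else resample_mask_to_grid(ds.tu, grid)
    wm = ds.wm if ds.wm.grid.is_compatible(grid) else resample_mask_to_grid(ds.wm, grid)

    ds_on_grid = dataclasses.replace(ds, maps=maps, tu=tu, wm=wm)
    maps = _filtered_maps(ds_on_grid, config)
    roi = build_roi_set(
        tu, wm, config.dilation_voxels, config.connectivity, config.nawm_erosion
    )

    ratio_maps = {n: m for n, m in maps.items() if n in MRSI_MAPS}
    usability = subject_usability_check(ratio_maps, roi, config.max_undefined_fraction)
    if not usability.passed:
        raise EmptyRegionError(
            f"subject {ds.subject_id} unusable: undefined fraction in TU+PT up to "
            f"{usability.worst:.0%} exceeds {config.max_undefined_fraction:.0%}"
        )

    summary = SubjectSummary(subject_id=ds.subject_id)
    hotspots: dict[str, dict[str, BinaryMask]] = {}
    for name, smap in maps.items():
        ref = nawm_reference_median(smap, roi.nawm)
        summary.nawm_medians[name] = region_summary(smap, roi.nawm)[0]
        hotspots[name] = {}
        for region in HOTSPOT_REGIONS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hs = define_hotspot(
                    smap, roi.region(region), ref, config.threshold_factor, name, region
                )
            if hs.is_empty:
                log.warning("empty hotspot: subject=%s map=%s region=%s", ds.subject_id,
                            name, region)
                continue
            hotspots[name][region] = hs.mask
            summary.hotspot_medians[(name, region)] = region_summary(smap, hs.mask)[0]

    # similarity: each map's hotspot vs the full segmentation of its region,
    # and each MRSI hotspot vs the T1/T2 hotspot in the same region
    for name in config.maps:
        for region in HOTSPOT_REGIONS:
            hs = hotspots.get(name, {}).get(region)
            if hs is None:
                continue
            seg = roi.region(region)
            summary.similarities.append(
                SimilarityRecord(
                    map_name=name, roi_name=region, comparator="roi",
                    dsc=dice(hs, seg), coid_cm=float("nan"),
                    n_a=hs.count, n_b=seg.count,
                    n_overlap=hs.intersection(seg).count,
                )
            )
            if name in MRSI_MAPS:
                for mrf in config.mrf_maps:
                    other = hotspots.get(mrf, {}).get(region)
                    if other is None:
                        continue
                    summary.similarities.append(
                        SimilarityRecord(
                            map_name=name, roi_name=region, comparator=mrf,
                            dsc=dice(hs, other),
                            coid_cm=coid(maps[name], hs, maps[mrf], other),
                            n_a=hs.count, n_b=other.count,
                            n_overlap=hs.intersection(other).count,
                        )
                    )
    return summary, roi, hotspots


# --------------------------------------------------------------------------
# Cohort run
# --------------------------------------------------------------------------

def discover_subjects(input_dir: str | Path) -> list[Path]:
    """Subject directories: immediate subdirectories containing tu.nii.gz."""
    root = Path(input_dir)
    subs = sorted(p for p in root.iterdir() if p.is_dir() and (p / "tu.nii.gz").exists())
    if not subs:
        raise ConfigError(f"no subject directories with tu.nii.gz under {root}")
    return subs


def run_pipeline(config: PipelineConfig) -> CohortTable:
    """Execute the full analysis and write all artifacts to the output dir."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    summaries: list[SubjectSummary] = []
    excluded: list[str] = []
    for sub_dir in discover_subjects(config.input_dir):
        ds = read_subject_dataset(sub_dir, config.maps)
        try:
            summary, _roi, hotspots = analyze_subject(ds, config)
        except EmptyRegionError as exc:
            log.warning("excluding subject %s: %s", sub_dir.name, exc)
            excluded.append(sub_dir.name)
            continue
        summaries.append(summary)
        if config.save_hotspots:
            hs_dir = out / "hotspots" / ds.subject_id
            hs_dir.mkdir(parents=True, exist_ok=True)
            for name, by_region in hotspots.items():
                for region, mask in by_region.items():
                    write_mask(mask, hs_dir / f"{name}_{region}_hotspot.nii.gz")
    if not summaries:
        raise EmptyRegionError("no usable subjects")

    table = build_report(summaries)
    subject_tidy_frame(summaries).to_csv(out / "subject_medians.tsv", sep="\t", index=False)
    similarity_tidy_frame(summaries).to_csv(out / "similarity.tsv", sep="\t", index=False)
    table.medians.to_csv(out / "cohort_medians.tsv", sep="\t", index=False)
    table.dsc.to_csv(out / "cohort_dsc.tsv", sep="\t", index=False)
    table.coid.to_csv(out / "cohort_coid.tsv", sep="\t", index=False)
    (out / "tables.txt").write_text(
        "Median values in regions of interest\n"
        + table.render_medians()
        + "\n\nDSCs between hotspots\n"
        + table.render_dsc()
        + "\n"
    )
    cfg = config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "config": cfg,
                "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "n_subjects": len(summaries),
                "excluded_subjects": excluded,
            },
            indent=2,
            default=str,
        )
    )
    return table
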