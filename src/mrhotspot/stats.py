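"""Per-region summaries, cohort aggregation, and the TU-vs-PT paired t-test.

Subject-level observations are hotspot medians (or un-thresholded NAWM
medians); the cohort is summarized by median and quartiles (linear
interpolation between order statistics).  TU and PT are compared per map
with a two-sided paired Student's t-test; subjects missing either member of
a pair are dropped pairwise.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyRegionError
from .similarity import SimilarityRecord
from .volumes import BinaryMask, ScalarMap

REGIONS = ("tu", "pt", "tu_pt", "nawm")
REGION_DISPLAY = {"tu": "TU", "pt": "PT", "tu_pt": "TU+PT", "nawm": "NAWM"}


def region_summary(smap: ScalarMap, mask: BinaryMask) -> tuple[float, float, float]:
    """(median, Q1, Q3) of the defined map values inside a mask."""
    vals = smap.values_in(mask)
    if vals.size == 0:
        raise EmptyRegionError("no defined voxels inside the region")
    med, q1, q3 = np.percentile(vals, [50, 25, 75])
    return float(med), float(q1), float(q3)


def cohort_aggregate(values: Iterable[float | None]) -> tuple[float, float, float, int]:
    """(median, Q1, Q3, n) over subjects, dropping missing observations."""
    arr = np.array([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise EmptyRegionError("no non-missing values to aggregate")
    med, q1, q3 = np.percentile(arr, [50, 25, 75])
    return float(med), float(q1), float(q3), int(arr.size)


@dataclasses.dataclass(frozen=True)
class PairedTTestResult:
    t: float
    p: float
    n: int
    degenerate: bool = False


def paired_t_test(
    x: Sequence[float | None], y: Sequence[float | None]
) -> PairedTTestResult:
    """Two-sided paired Student's t-test on complete pairs.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x − y and sample sd (n−1
    denominator); p from a Student t distribution with n−1 df.  Pairs with
    any missing member are dropped.  Zero variance of the differences is a
    degenerate case: flagged, with t and p undefined (NaN).
    """
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    pairs = [
        (a, b)
        for a, b in zip(x, y)
        if a is not None and b is not None and math.isfinite(a) and math.isfinite(b)
    ]
    n = len(pairs)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, got {n}")
    xs = np.array([a for a, _ in pairs])
    ys = np.array([b for _, b in pairs])
    if np.std(xs - ys, ddof=1) == 0:
        return PairedTTestResult(t=float("nan"), p=float("nan"), n=n, degenerate=True)
    t, p = sps.ttest_rel(xs, ys)
    return PairedTTestResult(t=float(t), p=float(p), n=n)


@dataclasses.dataclass
class SubjectSummary:
    """One subject's per-map observations feeding the cohort tables.

    ``hotspot_medians`` maps (map_name, region) -> median hotspot value;
    a missing key records an empty hotspot.  ``nawm_medians`` holds the
    un-thresholded NAWM region medians.  ``similarities`` holds the
    DSC/COID records for this subject.
    """

    subject_id: str
    hotspot_medians: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    nawm_medians: dict[str, float] = dataclasses.field(default_factory=dict)
    similarities: list[SimilarityRecord] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class CohortTable:
    """Cohort-level aggregation of subject summaries.

    ``medians`` is tidy (map, region, median, q1, q3, n); ``pvalues`` holds
    the per-map TU-vs-PT test; ``dsc`` and ``coid`` are tidy aggregates of
    the similarity records (map, comparator, region, median, q1, q3, n).
    """

    medians: pd.DataFrame
    pvalues: dict[str, PairedTTestResult]
    dsc: pd.DataFrame
    coid: pd.DataFrame

    def render_medians(self) -> str:
        """Human-readable medians table: rows = maps, columns TU | PT | p | TU+PT | NAWM."""
        maps = list(self.medians["map"].unique())
        rows = []
        for m in maps:
            row: dict[str, str] = {"Quantity": m}
            for region in ("tu", "pt", "tu_pt", "nawm"):
                row[REGION_DISPLAY[region]] = self._cell(m, region)
            res = self.pvalues.get(m)
            row["TU vs. PT p"] = (
                "degenerate" if res and res.degenerate else f"{res.p:.3g}" if res else "n/a"
            )
            rows.append(row)
        cols = ["Quantity", "TU", "PT", "TU vs. PT p", "TU+PT", "NAWM"]
        return pd.DataFrame(rows)[cols].to_string(index=False)

    def _cell(self, map_name: str, region: str) -> str:
        sel = self.medians[(self.medians["map"] == map_name) & (self.medians["region"] == region)]
        if sel.empty:
            return "missing"
        r = sel.iloc[0]
        return f"{r['median']:.3g} ({r['q1']:.3g}, {r['q3']:.3g})"

    def render_dsc(self) -> str:
        """DSC table: rows = map × comparator, columns = regions."""
        if self.dsc.empty:
            return "(no similarity records)"
        rows = []
        for (m, comp), grp in self.dsc.groupby(["map", "comparator"], sort=False):
            row = {"DSC between": f"{m} and {comp.upper() if comp != 'roi' else 'ROI'}"}
            for region in ("tu", "tu_pt", "pt"):
                sel = grp[grp["region"] == region]
                if sel.empty:
                    row[REGION_DISPLAY[region]] = "missing"
                else:
                    r = sel.iloc[0]
                    row[REGION_DISPLAY[region]] = f"{r['median']:.2f} ({r['q1']:.2f}, {r['q3']:.2f})"
            rows.append(row)
        return pd.DataFrame(rows).to_string(index=False)


def subject_tidy_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    """One row per subject × map × region hotspot median (plus NAWM medians)."""
    rows = []
    for s in summaries:
        for (m, region), v in sorted(s.hotspot_medians.items()):
            rows.append({"subject": s.subject_id, "map": m, "region": region, "median": v})
        for m, v in sorted(s.nawm_medians.items()):
            rows.append({"subject": s.subject_id, "map": m, "region": "nawm", "median": v})
    return pd.DataFrame(rows, columns=["subject", "map", "region", "median"])


def similarity_tidy_frame(summaries: Sequence[SubjectSummary]) -> pd.DataFrame:
    """One row per subject × similarity record."""
    rows = []
    for s in summaries:
        for rec in s.similarities:
            rows.append(
                {
                    "subject": s.subject_id,
                    "map": rec.map_name,
                    "region": rec.roi_name,
                    "comparator": rec.comparator,
                    "dsc": rec.dsc,
                    "coid_cm": rec.coid_cm,
                    "n_a": rec.n_a,
                    "n_b": rec.n_b,
                    "n_overlap": rec.n_overlap,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "map", "region", "comparator", "dsc", "coid_cm", "n_a", "n_b",
                 "n_overlap"],
    )


def _aggregate_column(df: pd.DataFrame, value_col: str, keys: list[str]) -> pd.DataFrame:
    rows = []
    if df.empty:
        return pd.DataFrame(columns=keys + ["median", "q1", "q3", "n"])
    for key_vals, grp in df.groupby(keys, sort=False):
        vals = grp[value_col].dropna()
        if vals.empty:
            continue
        med, q1, q3, n = cohort_aggregate(vals)
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row.update({"median": med, "q1": q1, "q3": q3, "n": n})
        rows.append(row)
    return pd.DataFrame(rows, columns=keys + ["median", "q1", "q3", "n"])


def build_report(summaries: Sequence[SubjectSummary]) -> CohortTable:
    """Aggregate subject summaries into the cohort tables.

    Subjects without a non-empty hotspot for a (map, region) are missing
    for that cell and dropped pairwise in the TU-vs-PT test.
    """
    if not summaries:
        raise ValueError("need at least one subject")
    tidy = subject_tidy_frame(summaries)
    medians = _aggregate_column(tidy, "median", ["map", "region"])

    maps = sorted({m for s in summaries for (m, _) in s.hotspot_medians})
    pvalues: dict[str, PairedTTestResult] = {}
    for m in maps:
        x = [s.hotspot_medians.get((m, "tu")) for s in summaries]
        y = [s.hotspot_medians.get((m, "pt")) for s in summaries]
        try:
            pvalues[m] = paired_t_test(x, y)
        except ValueError:
            continue  # fewer than 2 complete pairs: no test for this map

    sim = similarity_tidy_frame(summaries)
    dsc = _aggregate_column(sim, "dsc", ["map", "comparator", "region"])
    coid_df = _aggregate_column(
        sim[np.isfinite(sim["coid_cm"].astype(float))] if not sim.empty else sim,
        "coid_cm",
        ["map", "comparator", "region"],
    )
    return CohortTable(medians=medians, pvalues=pvalues, dsc=dsc, coid=coid_df)
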