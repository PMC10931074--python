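"""Region summaries, cohort aggregation, the paired t-test (against an
independent textbook-formula oracle), and cohort report assembly."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from mrhotspot import (
    BinaryMask,
    Grid,
    ScalarMap,
    SubjectSummary,
    build_report,
    cohort_aggregate,
    paired_t_test,
    region_summary,
)
from mrhotspot.errors import EmptyRegionError
from mrhotspot.similarity import SimilarityRecord


def t_test_oracle(x, y):
    """Independent implementation of the paired two-sided Student t-test."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    sd = math.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


def line_map(values):
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    g = Grid(arr.shape, (1, 1, 1))
    return ScalarMap(g, arr, "ratio"), BinaryMask(g, np.ones(arr.shape, bool))


class TestRegionSummary:
    def test_interpolated_quartiles(self):
        m, mask = line_map([1, 2, 3, 4, 5])
        assert region_summary(m, mask) == (3.0, 2.0, 4.0)

    def test_constant_map(self):
        m, mask = line_map([7, 7, 7])
        assert region_summary(m, mask) == (7.0, 7.0, 7.0)

    def test_single_voxel(self):
        m, mask = line_map([4.2])
        assert region_summary(m, mask) == (4.2, 4.2, 4.2)

    def test_matches_sorted_interpolation_oracle(self, rng):
        for _ in range(30):
            vals = rng.random(rng.integers(2, 40))
            m, mask = line_map(vals)
            med, q1, q3 = region_summary(m, mask)
            s = np.sort(vals)

            def interp_quantile(q):
                h = (len(s) - 1) * q
                lo = int(np.floor(h))
                hi = min(lo + 1, len(s) - 1)
                return s[lo] + (h - lo) * (s[hi] - s[lo])

            assert med == pytest.approx(interp_quantile(0.5))
            assert q1 == pytest.approx(interp_quantile(0.25))
            assert q3 == pytest.approx(interp_quantile(0.75))

    def test_empty_region_errors(self):
        m, _ = line_map([np.nan, np.nan])
        g = m.grid
        with pytest.raises(EmptyRegionError):
            region_summary(m, BinaryMask(g, np.ones(g.shape, bool)))


class TestCohortAggregate:
    def test_single_value(self):
        assert cohort_aggregate([0.5]) == (0.5, 0.5, 0.5, 1)

    def test_missing_dropped_with_bookkeeping(self):
        med, q1, q3, n = cohort_aggregate([1.0, None, 2.0, np.nan, 3.0])
        assert (med, n) == (2.0, 3)

    def test_twelve_subject_cohort_matches_oracle(self, rng):
        vals = rng.random(12)
        med, q1, q3, n = cohort_aggregate(vals)
        assert n == 12
        assert (med, q1, q3) == tuple(np.percentile(vals, [50, 25, 75]))

    def test_all_missing_errors(self):
        with pytest.raises(EmptyRegionError):
            cohort_aggregate([None, np.nan])


class TestPairedTTest:
    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0.6, 0.1, size=12)
            y = rng.normal(0.4, 0.1, size=12)
            res = paired_t_test(list(x), list(y))
            t_ref, p_ref = t_test_oracle(x, y)
            assert res.t == pytest.approx(t_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)
            assert res.n == 12

    def test_constant_difference_degenerate(self):
        res = paired_t_test([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])
        assert res.degenerate
        assert math.isnan(res.p)

    def test_zero_difference_degenerate(self):
        res = paired_t_test([1.0] * 4, [1.0] * 4)
        assert res.degenerate

    def test_missing_pairs_dropped(self, rng):
        x = [1.0, None, 2.0, 3.0, 4.0]
        y = [0.5, 1.0, None, 2.0, 3.5]
        res = paired_t_test(x, y)
        assert res.n == 3

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, None], [2.0, 3.0])

    def test_two_sided_symmetry_and_shift_invariance(self, rng):
        x = list(rng.normal(size=10))
        y = list(rng.normal(size=10))
        a = paired_t_test(x, y)
        b = paired_t_test(y, x)
        assert a.p == pytest.approx(b.p)
        assert a.t == pytest.approx(-b.t)
        shifted = paired_t_test([v + 5 for v in x], [v + 5 for v in y])
        assert shifted.p == pytest.approx(a.p)


def _summary(i, tu, pt, dsc=0.8):
    s = SubjectSummary(subject_id=f"sub-{i:02d}")
    s.hotspot_medians[("gln_tnaa", "tu")] = tu
    if pt is not None:
        s.hotspot_medians[("gln_tnaa", "pt")] = pt
    s.nawm_medians["gln_tnaa"] = 0.16
    s.similarities.append(
        SimilarityRecord("gln_tnaa", "tu", "t1", dsc, 0.3, 10, 12, 9)
    )
    return s


class TestBuildReport:
    def test_single_subject_quartiles_collapse(self):
        table = build_report([_summary(1, 0.6, 0.4)])
        row = table.medians[(table.medians["map"] == "gln_tnaa")
                            & (table.medians["region"] == "tu")].iloc[0]
        assert row["median"] == row["q1"] == row["q3"] == 0.6

    def test_cells_equal_recomputation_from_subject_records(self, rng):
        tus = rng.normal(0.6, 0.05, 12)
        pts = rng.normal(0.4, 0.05, 12)
        summaries = [_summary(i, tu, pt) for i, (tu, pt) in enumerate(zip(tus, pts))]
        table = build_report(summaries)
        row = table.medians[(table.medians["map"] == "gln_tnaa")
                            & (table.medians["region"] == "tu")].iloc[0]
        assert row["median"] == pytest.approx(np.median(tus))
        res = table.pvalues["gln_tnaa"]
        t_ref, p_ref = t_test_oracle(tus, pts)
        assert res.p == pytest.approx(p_ref, abs=1e-12)
        dsc_row = table.dsc.iloc[0]
        assert dsc_row["median"] == 0.8
        assert dsc_row["n"] == 12

    def test_missing_hotspots_reported_missing_not_zero(self):
        summaries = [_summary(i, 0.6 + 0.01 * i, None) for i in range(4)]
        table = build_report(summaries)
        assert not ((table.medians["map"] == "gln_tnaa")
                    & (table.medians["region"] == "pt")).any()
        assert "gln_tnaa" not in table.pvalues  # no complete TU/PT pairs
        assert "missing" in table.render_medians()

    def test_pairwise_deletion_in_test(self):
        summaries = [_summary(i, 0.6, 0.4 + 0.01 * i) for i in range(5)]
        summaries.append(_summary(9, 0.7, None))
        table = build_report(summaries)
        assert table.pvalues["gln_tnaa"].n == 5
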