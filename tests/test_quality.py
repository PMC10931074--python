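"""MRSI voxel rejection rules, MAD outlier filter, ratio-map domain logic,
and the subject usability check."""

import dataclasses

import numpy as np
import pytest

from mrhotspot import (
    BinaryMask,
    Grid,
    PhantomSpec,
    QualityRule,
    ScalarMap,
    apply_quality_rule,
    build_roi_set,
    generate_subject,
    mad_outlier_mask,
    ratio_map,
    subject_usability_check,
)
from mrhotspot.errors import EmptyRegionError, QualityMapMissingError

from conftest import make_map


def flat_map(values, unit="unitless"):
    """1D value list as a (n,1,1) ScalarMap."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    g = Grid(arr.shape, (1, 1, 1))
    return ScalarMap(g, arr, unit)


class TestMadOutlierMask:
    def test_zero_mad_rejects_nothing(self):
        m = flat_map([1, 1, 1, 1, 100])
        assert mad_outlier_mask(m, 13).is_empty

    def test_extreme_outlier_rejected_exactly(self):
        vals = list(range(1, 101)) + [10**6]
        rejected = mad_outlier_mask(flat_map(vals), 13)
        assert rejected.count == 1
        assert rejected.members[100, 0, 0]

    def test_huge_k_rejects_nothing(self, rng):
        m = flat_map(rng.random(50))
        assert mad_outlier_mask(m, 1e12).is_empty

    def test_all_undefined_errors(self, grid):
        m = make_map(grid, np.nan)
        with pytest.raises(EmptyRegionError):
            mad_outlier_mask(m, 13)


class TestApplyQualityRule:
    @staticmethod
    def _subject(defects):
        spec = PhantomSpec(shape=(16, 16, 12), defect_fractions=defects, noise_cv=0.0)
        return generate_subject(spec, seed=11)

    def test_planted_snr_violations_rejected_exactly(self):
        ds, truth = self._subject({"fwhm": 0, "snr": 0.1, "crlb": 0, "fit": 0})
        accepted = apply_quality_rule("gln", ds.quality, QualityRule())
        brain = truth.region_masks["brain"].members
        rejected = brain & ~accepted.members
        assert np.array_equal(rejected, truth.rejected_snr.members)

    @pytest.mark.parametrize("rule_name", ["fwhm", "crlb", "fit"])
    def test_planted_single_rule_violations_recovered(self, rule_name):
        ds, truth = self._subject({rule_name: 0.05})
        accepted = apply_quality_rule("gly", ds.quality, QualityRule())
        brain = truth.region_masks["brain"].members
        rejected = brain & ~accepted.members
        planted = {
            "fwhm": truth.rejected_fwhm.members,
            "crlb": truth.rejected_crlb["gly"].members,
            "fit": truth.rejected_fit["gly"].members,
        }[rule_name]
        assert np.array_equal(rejected, planted)

    def test_perfect_quality_accepts_whole_domain(self):
        ds, truth = self._subject({"fwhm": 0, "snr": 0, "crlb": 0, "fit": 0})
        accepted = apply_quality_rule("tnaa", ds.quality, QualityRule())
        assert np.array_equal(accepted.members, ds.quality.fwhm_tcr.domain)

    def test_crlb_all_100_rejects_everything(self, grid):
        from mrhotspot import QualityMaps

        q = QualityMaps(
            fwhm_tcr=make_map(grid, 0.05, "ppm"),
            snr_tcr=make_map(grid, 20.0, "unitless"),
            crlb={"gln": make_map(grid, 100.0, "unitless")},
            fit_coeff={"gln": make_map(grid, 0.0, "unitless")},
        )
        assert apply_quality_rule("gln", q, QualityRule()).is_empty

    def test_missing_quality_map_errors(self):
        ds, _ = self._subject({})
        with pytest.raises(QualityMapMissingError):
            apply_quality_rule("lactate", ds.quality, QualityRule())

    def test_acceptance_monotone_in_each_threshold(self):
        ds, _ = self._subject({"fwhm": 0.05, "snr": 0.05, "crlb": 0.05, "fit": 0.02})
        base = QualityRule()
        accepted = apply_quality_rule("ins", ds.quality, base)
        looser = [
            dataclasses.replace(base, fwhm_max=base.fwhm_max * 2),
            dataclasses.replace(base, snr_min=base.snr_min / 2),
            dataclasses.replace(base, crlb_max=base.crlb_max * 1.2),
            dataclasses.replace(base, mad_k=base.mad_k * 2),
        ]
        for rule in looser:
            assert accepted.issubset(apply_quality_rule("ins", ds.quality, rule))


class TestRatioMap:
    def test_constant_ratio(self, grid):
        out = ratio_map(make_map(grid, 2.0), make_map(grid, 4.0))
        assert np.allclose(out.defined_values(), 0.5)
        assert out.unit == "ratio"
        assert out.n_defined == grid.n_voxels

    def test_zero_denominator_undefined(self, grid):
        den_vals = np.full(grid.shape, 4.0)
        den_vals[0, 0, 0] = 0.0
        out = ratio_map(make_map(grid, 2.0), make_map(grid, den_vals))
        assert not out.domain[0, 0, 0]
        assert out.n_defined == grid.n_voxels - 1

    def test_domain_is_set_conjunction(self, grid, rng):
        """Defined domain = accept(num) ∩ accept(den) ∩ {den > 0}, voxel-wise."""
        for _ in range(10):
            num = make_map(grid, rng.random(grid.shape))
            den_vals = rng.random(grid.shape) - 0.1  # some non-positive voxels
            den = make_map(grid, den_vals)
            acc_n = BinaryMask(grid, rng.random(grid.shape) < 0.8)
            acc_d = BinaryMask(grid, rng.random(grid.shape) < 0.8)
            out = ratio_map(num, den, acc_n, acc_d)
            expected = acc_n.members & acc_d.members & (den_vals > 0)
            assert np.array_equal(out.domain, expected)
            assert np.allclose(
                out.values[expected], num.values[expected] / den_vals[expected]
            )


class TestUsabilityCheck:
    @staticmethod
    def _roi():
        g = Grid((20, 20, 20), (3.4, 3.4, 3.4))
        tu = np.zeros(g.shape, bool)
        tu[8:12, 8:12, 8:12] = True
        return g, build_roi_set(BinaryMask(g, tu), BinaryMask(g, np.ones(g.shape, bool)),
                                dilation_voxels=2)

    def test_fully_defined_passes_with_zero_fractions(self):
        g, roi = self._roi()
        report = subject_usability_check({"a": make_map(g, 1.0)}, roi)
        assert report.passed
        assert report.undefined_fractions == {"a": 0.0}

    def test_planted_undefined_fraction_fails(self, rng):
        g, roi = self._roi()
        vals = np.ones(g.shape)
        region = np.argwhere(roi.tu_pt.members)
        kill = region[rng.permutation(len(region))[: int(0.6 * len(region))]]
        vals[tuple(kill.T)] = np.nan
        report = subject_usability_check({"a": make_map(g, vals)}, roi,
                                         max_undefined_fraction=0.5)
        assert not report.passed
        assert report.undefined_fractions["a"] == pytest.approx(0.6, abs=0.01)

    def test_threshold_one_always_passes(self):
        g, roi = self._roi()
        report = subject_usability_check({"a": make_map(g, np.nan)}, roi,
                                         max_undefined_fraction=1.0)
        assert report.passed
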