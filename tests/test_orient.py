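"""Circular-statistics tests: angles, sector rule, rose bins, Kuiper,
two-proportion comparison and the orientation pipeline."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from centroquant import (
    DegenerateDataError,
    ParameterError,
    circular_summary,
    classify_sector,
    kuiper_uniformity,
    orientation_angle,
    orientation_pipeline,
    rose_histogram,
    sample_orientation_angles,
    two_proportion_test,
)
from centroquant.detect import cells_from_table

# Frozen from R: prop.test(c(161,167), c(230,309), alternative="greater",
# correct=TRUE)$p.value and the two-sided / uncorrected variants
R_PROP_ONE_SIDED = 1.239669e-4
R_PROP_TWO_SIDED = 2.479337e-4
R_CHI2_NO_CC = 14.0895025932


class TestOrientationAngle:
    def test_along_normal_is_zero(self):
        assert orientation_angle((0, 0), (0, 1), (0, 1)) == pytest.approx(0.0)

    def test_ccw_quarter_turn_is_plus_ninety(self):
        # normal +x, centrosome displaced along +y (CCW from +x)
        assert orientation_angle((0, 0), (1, 0), (0, 1)) == pytest.approx(90.0)

    def test_opposite_normal_is_180(self):
        assert orientation_angle((0, 0), (0, -1), (0, 1)) == pytest.approx(180.0)

    def test_degenerate_vector_raises(self):
        with pytest.raises(DegenerateDataError):
            orientation_angle((1.0, 2.0), (1.0, 2.0), (0, 1))

    def test_invariant_under_rigid_rotation(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            nuc = rng.uniform(-10, 10, 2)
            cen = nuc + rng.uniform(-5, 5, 2)
            phi = rng.uniform(0, 2 * math.pi)
            n = np.array([math.sin(phi), math.cos(phi)])
            base = orientation_angle(nuc, cen, n)
            rot = rng.uniform(0, 2 * math.pi)
            c, s = math.cos(rot), math.sin(rot)

            def R(v):  # rotate (y, x) CCW by rot
                return np.array([s * v[1] + c * v[0], c * v[1] - s * v[0]])

            rotated = orientation_angle(R(nuc), R(cen), R(n))
            assert abs(rotated - base) < 1e-9 or abs(abs(rotated - base) - 360) < 1e-9


class TestSectorAndRose:
    def test_sector_boundary_inclusive(self):
        assert classify_sector(0.0)
        assert classify_sector(75.0)
        assert classify_sector(-75.0)
        assert not classify_sector(75.0001)
        assert not classify_sector(180.0)

    def test_rose_example_bins(self):
        rose = rose_histogram([0.0, 10.0, 20.0])
        assert rose.counts[12] == 2  # [0, 15)
        assert rose.counts[13] == 1  # [15, 30)
        assert rose.counts.sum() == 3

    def test_plus_180_folds_into_top_bin(self):
        rose = rose_histogram([180.0])
        assert rose.counts[23] == 1

    def test_empty_histogram_is_all_zero(self):
        rose = rose_histogram([])
        assert rose.counts.sum() == 0
        assert np.all(rose.relative_radius == 0.0)

    def test_uniform_angles_fill_bins_evenly(self):
        a = sample_orientation_angles(100_000, 0.0, 0.0, seed=10)
        rose = rose_histogram(a)
        assert np.all(np.abs(rose.counts - len(a) / 24) < 0.05 * len(a) / 24)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-179.999, 180.0), min_size=0, max_size=200))
    def test_counts_conserved(self, angles):
        assert rose_histogram(angles).counts.sum() == len(angles)


class TestCircularSummary:
    def test_constant_angles(self):
        mean, r = circular_summary([40.0] * 12)
        assert mean == pytest.approx(40.0)
        assert r == pytest.approx(1.0)

    def test_antipodal_pair_undefined_mean(self):
        mean, r = circular_summary([90.0, -90.0])
        assert mean is None and r == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_mean_recovered(self):
        a = sample_orientation_angles(100_000, 1.0, 0.0, seed=11)
        mean, r = circular_summary(a)
        assert abs(mean) < 1.0
        assert 0 < r < 1

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            circular_summary([])


class TestKuiper:
    def test_single_observation_v_is_one(self):
        for angle in (-170.0, 0.0, 33.0, 180.0):
            v, _p = kuiper_uniformity([angle])
            assert v == pytest.approx(1.0)

    def test_rotation_invariance_of_v(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(-180, 180, 80)
        v0, _ = kuiper_uniformity(a)
        for shift in (10.0, 97.3, 255.0):
            shifted = np.mod(a + shift + 180.0, 360.0) - 180.0
            v, _ = kuiper_uniformity(shifted)
            assert v == pytest.approx(v0, abs=1e-12)

    def test_power_against_concentrated_alternative(self):
        for seed in range(5):
            a = sample_orientation_angles(200, 1.0, 0.0, seed=seed)
            _v, p = kuiper_uniformity(a)
            assert p < 0.001

    def test_null_rejection_rate_roughly_five_percent(self):
        rng = np.random.default_rng(13)
        rejections = 0
        runs = 400
        for _ in range(runs):
            a = rng.uniform(-180, 180, 50)
            _v, p = kuiper_uniformity(a)
            rejections += p < 0.05
        assert 0.02 <= rejections / runs <= 0.09

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            kuiper_uniformity([])


class TestTwoProportionTest:
    def test_reconstructed_wound_assay_counts_match_reference(self):
        res = two_proportion_test(161, 230, 167, 309, continuity=True)
        assert res.p_one_sided == pytest.approx(R_PROP_ONE_SIDED, rel=1e-3)
        assert res.p_two_sided == pytest.approx(R_PROP_TWO_SIDED, rel=1e-3)
        # the one-sided value reproduces the printed p = 0.000124
        assert round(res.p_one_sided, 6) == 0.000124

    def test_no_continuity_equals_pearson_chi2(self):
        res = two_proportion_test(161, 230, 167, 309, continuity=False)
        table = np.array([[161, 230 - 161], [167, 309 - 167]])
        chi2 = chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(chi2.statistic, abs=1e-10)
        assert res.p_two_sided == pytest.approx(chi2.pvalue, abs=1e-10)
        assert res.statistic == pytest.approx(R_CHI2_NO_CC, abs=1e-6)

    def test_continuity_matches_yates_chi2(self):
        res = two_proportion_test(30, 80, 45, 90, continuity=True)
        table = np.array([[30, 50], [45, 45]])
        chi2 = chi2_contingency(table, correction=True)
        assert res.statistic == pytest.approx(chi2.statistic, abs=1e-10)

    def test_equal_proportions_clamp_to_one(self):
        res = two_proportion_test(50, 100, 50, 100)
        assert res.statistic == 0.0
        assert res.p_two_sided == 1.0

    def test_extreme_difference_significant(self):
        res = two_proportion_test(0, 10, 10, 10)
        assert res.p_two_sided < 1e-3
        assert res.direction == "p2_greater"

    def test_degenerate_pooled_proportion(self):
        res = two_proportion_test(10, 10, 5, 5)
        assert res.p_two_sided == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            two_proportion_test(5, 4, 1, 10)


def _cells_along_normals(angles_deg):
    """Outer cells whose centrosome sits at the given angle from +x."""
    rows = []
    for i, a in enumerate(angles_deg):
        t = math.radians(a)
        rows.append({
            "cell_id": i,
            "nucleus_y_um": 30.0 * i,
            "nucleus_x_um": 0.0,
            "centrosome_y_um": 30.0 * i + 5 * math.sin(t),
            "centrosome_x_um": 5 * math.cos(t),
            "zone": "outer",
            "wound_normal_y": 0.0,
            "wound_normal_x": 1.0,
        })
    return cells_from_table(pd.DataFrame(rows))


class TestOrientationPipeline:
    def test_all_along_normal_gives_full_sector_and_unit_r(self):
        result, table = orientation_pipeline(_cells_along_normals([0.0] * 20))
        assert result.prop_in_sector == 1.0
        assert result.resultant_R == pytest.approx(1.0)
        assert result.circ_mean_deg == pytest.approx(0.0, abs=1e-9)
        assert table.in_sector.all()

    def test_prop_equals_mean_of_sector_calls(self):
        angles = sample_orientation_angles(150, 0.8, 0.0, seed=14)
        result, table = orientation_pipeline(_cells_along_normals(angles))
        assert result.prop_in_sector == pytest.approx(table.in_sector.mean())
        assert result.n == result.rose.n

    def test_recovered_angles_match_input(self):
        angles = sample_orientation_angles(64, 1.2, 0.0, seed=15)
        _result, table = orientation_pipeline(_cells_along_normals(angles))
        assert np.allclose(np.sort(table.angle_deg), np.sort(angles), atol=1e-9)

    def test_zero_eligible_cells_raises_with_filter_name(self):
        cells = _cells_along_normals([0.0, 10.0])
        cells["zone"] = "inner"
        with pytest.raises(DegenerateDataError, match="outer"):
            orientation_pipeline(cells)

    def test_ground_truth_control_field_concentration(self, control_field):
        from centroquant.detect import cells_from_field

        result, _ = orientation_pipeline(cells_from_field(control_field),
                                         zone_filter=None)
        # n=80 cells at kappa ~ 0.98: expect ~70% in sector
        se = math.sqrt(0.7 * 0.3 / result.n)
        assert abs(result.prop_in_sector - 0.698) < 4 * se
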