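"""Detection-stage tests: segmentation, spot finding, assignment, zones."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from centroquant import (
    ImageStack,
    NoWoundError,
    ParameterError,
    SynthConfig,
    WoundGeometry,
    assign_centrosome,
    call_detectable,
    classify_zone,
    control_kappa,
    detect_spots,
    estimate_wound_edge,
    generate_field,
    pair_centrioles,
    project_z_sd,
    render_stack,
    segment_nuclei,
)
from centroquant.detect import SpotSet, cells_from_field, cells_from_segmentation


def _field_frame_segmentation(stack, origin):
    proj = project_z_sd(stack, "dapi")
    labels, table = segment_nuclei(proj, stack.voxel_um[1:])
    table = table.copy()
    table["centroid_y_um"] += origin[1]
    table["centroid_x_um"] += origin[2]
    return labels, table


class TestSegmentNuclei:
    def test_blank_image_gives_no_labels(self):
        labels, table = segment_nuclei(np.zeros((64, 64)), (0.3, 0.3))
        assert labels.max() == 0 and len(table) == 0

    def test_round_trip_centroids_within_one_micron(self, rendered_bundle):
        field, stack, origin = rendered_bundle
        _labels, table = _field_frame_segmentation(stack, origin)
        gt = field.cells[["nucleus_y_um", "nucleus_x_um"]].to_numpy()
        det = table[["centroid_y_um", "centroid_x_um"]].to_numpy()
        assert len(table) == len(gt)
        d, _ = cKDTree(det).query(gt)
        assert (d < 1.0).all()

    def test_equivalent_diameter_close_to_truth(self, rendered_bundle):
        field, stack, origin = rendered_bundle
        _labels, table = _field_frame_segmentation(stack, origin)
        true_diam = 2 * field.config.nucleus_radius_um
        assert np.median(table.equiv_diameter_um) == pytest.approx(true_diam,
                                                                   rel=0.1)

    def test_touching_nuclei_split_by_watershed(self):
        # two nuclei at 2.3 x radius separation, rendered without noise
        cfg = SynthConfig(n_cells=2, spots_per_cell=0, noise=(0.0, 0.0),
                          min_spacing_factor=2.3, field_size_um=(40.0, 12.0),
                          seed=12)
        field = generate_field(cfg)
        # force exact 2.3 r separation side by side
        cells = field.cells.copy()
        cells.loc[0, ["nucleus_y_um", "nucleus_x_um"]] = (40.0, 30.0)
        cells.loc[1, ["nucleus_y_um", "nucleus_x_um"]] = (40.0, 30.0 + 2.3 * 5.0)
        field.cells = cells
        stack = render_stack(field)
        proj = project_z_sd(stack, "dapi")
        _labels, table = segment_nuclei(proj, stack.voxel_um[1:])
        assert len(table) == 2


class TestDetectSpots:
    def test_noiseless_punctum_within_half_voxel(self):
        cfg = SynthConfig(n_cells=1, spots_per_cell=0, noise=(0.0, 0.0), seed=7)
        field = generate_field(cfg)
        stack = render_stack(field)
        spots = detect_spots(stack, "centrosome")
        assert len(spots) == 1
        truth = field.cells[["centrosome_z_um", "centrosome_y_um",
                             "centrosome_x_um"]].to_numpy()[0]
        err = np.abs(spots.coords_um[0] + np.array(stack.origin_um) - truth)
        assert (err <= 0.5 * np.array(stack.voxel_um)).all()

    def test_pure_noise_yields_no_spots(self):
        clean = 0
        n_runs = 30
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            img = rng.poisson(20.0, (9, 128, 128)) + rng.normal(0, 2, (9, 128, 128))
            stack = ImageStack(img[None].astype(np.float32),
                               voxel_um=(0.6, 0.2841, 0.2841))
            if len(detect_spots(stack, 0, threshold_k=5.0)) == 0:
                clean += 1
        assert clean >= n_runs - 1

    def test_round_trip_recall_precision(self, rendered_bundle):
        field, stack, origin = rendered_bundle
        spots = pair_centrioles(detect_spots(stack, "centrosome"))
        coords = spots.coords_um + origin
        gt = field.cells[["centrosome_z_um", "centrosome_y_um",
                          "centrosome_x_um"]].to_numpy()
        d, _ = cKDTree(gt).query(coords)
        matched = (d <= 0.6).sum()  # two lateral voxels
        assert matched / len(gt) >= 0.95
        assert matched / len(coords) >= 0.95

    def test_subvoxel_scale_rejected(self, rendered_bundle):
        _field, stack, _origin = rendered_bundle
        with pytest.raises(ParameterError):
            detect_spots(stack, "centrosome", sigma_um=(0.1, 0.05, 0.05))


class TestPairCentrioles:
    def _spotset(self, coords, amps):
        return SpotSet(channel="c", coords_um=np.asarray(coords, float),
                       amplitude=np.asarray(amps, float))

    def test_close_pair_merges_to_weighted_centroid(self):
        merged = pair_centrioles(
            self._spotset([[0, 0, 0], [0, 0, 0.3]], [1.0, 1.0]), 1.0)
        assert len(merged) == 1
        np.testing.assert_allclose(merged.coords_um[0], [0, 0, 0.15])

    def test_unequal_amplitudes_weight_the_centroid(self):
        merged = pair_centrioles(
            self._spotset([[0, 0, 0], [0, 0, 1.0]], [3.0, 1.0]), 1.5)
        np.testing.assert_allclose(merged.coords_um[0], [0, 0, 0.25])

    def test_distant_spots_pass_through(self):
        out = pair_centrioles(
            self._spotset([[0, 0, 0], [0, 0, 1.5]], [1.0, 2.0]), 1.0)
        assert len(out) == 2

    def test_empty_input_empty_output(self):
        out = pair_centrioles(self._spotset(np.zeros((0, 3)), []), 1.0)
        assert len(out) == 0


class TestAssignCentrosome:
    def _cells(self, centroids):
        return cells_from_segmentation(pd.DataFrame({
            "label": np.arange(1, len(centroids) + 1),
            "centroid_y_um": [c[0] for c in centroids],
            "centroid_x_um": [c[1] for c in centroids],
            "area_um2": 78.5,
            "equiv_diameter_um": 10.0,
        }))

    def test_within_range_assigned(self):
        cells = assign_centrosome(
            self._cells([(0.0, 0.0)]),
            SpotSet(channel="c", coords_um=[[0, 0, 5.0]], amplitude=[2.0]),
            max_dist_um=15.0)
        assert cells.centrosome_x_um.iloc[0] == pytest.approx(5.0)

    def test_beyond_max_dist_unassigned(self):
        cells = assign_centrosome(
            self._cells([(0.0, 0.0)]),
            SpotSet(channel="c", coords_um=[[0, 0, 20.0]], amplitude=[2.0]),
            max_dist_um=15.0)
        assert np.isnan(cells.centrosome_x_um.iloc[0])
        assert not cells.detectable.iloc[0]

    def test_brightest_of_two_kept(self):
        cells = assign_centrosome(
            self._cells([(0.0, 0.0)]),
            SpotSet(channel="c", coords_um=[[0, 0, 3.0], [0, 4.0, 0]],
                    amplitude=[7.0, 10.0]),
            max_dist_um=15.0)
        assert cells.centrosome_amp.iloc[0] == pytest.approx(10.0)
        assert cells.centrosome_y_um.iloc[0] == pytest.approx(4.0)

    def test_stable_under_spot_permutation(self):
        coords = [[0, 0, 3.0], [0, 4.0, 0], [0, 30.0, 30.0]]
        amps = [7.0, 10.0, 5.0]
        a = assign_centrosome(
            self._cells([(0.0, 0.0), (30.0, 30.0)]),
            SpotSet(channel="c", coords_um=coords, amplitude=amps))
        perm = [2, 0, 1]
        b = assign_centrosome(
            self._cells([(0.0, 0.0), (30.0, 30.0)]),
            SpotSet(channel="c", coords_um=[coords[i] for i in perm],
                    amplitude=[amps[i] for i in perm]))
        pd.testing.assert_frame_equal(a, b)


class TestWoundAndZones:
    def test_estimated_band_close_to_truth(self, rendered_bundle):
        field, stack, origin = rendered_bundle
        _labels, table = _field_frame_segmentation(stack, origin)
        pts = table[["centroid_y_um", "centroid_x_um"]].to_numpy()
        inset = 0.5 * float(np.median(table.equiv_diameter_um))
        wound = estimate_wound_edge(pts, edge_inset_um=inset)
        nn, _ = cKDTree(pts).query(pts, k=2)
        spacing = float(np.median(nn[:, 1]))
        # same orientation up to sign
        assert abs(abs(np.dot(wound.normal, field.wound.normal)) - 1) < 0.01
        true_lo, true_hi = field.wound.band
        # map detected offsets into the true normal's frame (sign-ambiguous)
        sign = np.sign(np.dot(wound.normal, field.wound.normal))
        det_lo, det_hi = sorted((sign * wound.band[0], sign * wound.band[1]))
        assert abs(det_lo - true_lo) < spacing
        assert abs(det_hi - true_hi) < spacing

    def test_confluent_field_has_no_wound(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 200, (150, 2))
        with pytest.raises(NoWoundError):
            estimate_wound_edge(pts)

    def test_boundary_cell_is_outer_inclusive(self):
        wound = WoundGeometry(axis=(0.0, 1.0), normal=(1.0, 0.0),
                              band=(-20.0, 20.0))
        cells = pd.DataFrame({
            "cell_id": [0, 1, 2],
            "nucleus_y_um": [35.0, 20.0, 170.0],  # d_outer=15: 15, 0, 150
            "nucleus_x_um": [0.0, 0.0, 0.0],
        })
        from centroquant.detect import cells_from_table

        out = classify_zone(cells_from_table(cells), wound, d_outer_um=15.0)
        assert list(out.zone) == ["outer", "outer", "inner"]
        # normals point toward the wound
        assert out.wound_normal_y.iloc[0] == pytest.approx(-1.0)

    def test_zone_labels_match_generator_truth(self, control_field):
        cells = cells_from_field(control_field)
        relabeled = classify_zone(cells, control_field.wound,
                                  d_outer_um=control_field.config.d_outer_um)
        assert (relabeled.zone.to_numpy()
                == control_field.cells.zone.to_numpy()).all()


class TestCallDetectable:
    def test_fraction_arithmetic(self):
        from centroquant.detect import cells_from_table

        cells = cells_from_table(pd.DataFrame({
            "cell_id": range(10),
            "nucleus_y_um": np.arange(10.0),
            "nucleus_x_um": 0.0,
            "zone": ["outer"] * 10,
            "centrosome_y_um": [0.0] * 10,
            "centrosome_x_um": [0.0] * 10,
            "centrosome_response": [10.0] * 7 + [0.1] * 3,
        }))
        spotset = SpotSet(channel="c", coords_um=np.zeros((0, 3)), amplitude=[],
                          threshold_k=5.0, response_median=0.0,
                          response_sigma=0.2)
        out, pct = call_detectable(cells, spotset)
        assert pct == pytest.approx(70.0)
        assert out.detectable.sum() == 7

    def test_no_outer_cells_reports_missing(self):
        from centroquant.detect import cells_from_table

        cells = cells_from_table(pd.DataFrame({
            "cell_id": [0], "nucleus_y_um": [0.0], "nucleus_x_um": [0.0],
            "zone": ["inner"], "centrosome_y_um": [0.0],
            "centrosome_x_um": [0.0], "centrosome_response": [10.0],
        }))
        spotset = SpotSet(channel="c", coords_um=np.zeros((0, 3)), amplitude=[],
                          response_median=0.0, response_sigma=0.2)
        _out, pct = call_detectable(cells, spotset)
        assert pct is None

    def test_all_rendered_centrosomes_detectable(self, rendered_bundle):
        field, stack, origin = rendered_bundle
        _labels, table = _field_frame_segmentation(stack, origin)
        cells = cells_from_segmentation(table)
        spots = detect_spots(stack, "centrosome")
        spots.coords_um = spots.coords_um + origin
        cents = pair_centrioles(spots)
        cells = assign_centrosome(cells, cents)
        inset = 0.5 * float(np.median(table.equiv_diameter_um))
        wound = estimate_wound_edge(
            cells[["nucleus_y_um", "nucleus_x_um"]].to_numpy(), edge_inset_um=inset)
        cells = classify_zone(cells, wound)
        _cells, pct = call_detectable(cells, cents)
        assert pct == pytest.approx(100.0)
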