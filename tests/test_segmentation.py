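"""Tests of depot segmentation: region growing, VAT delineation, the
deep/superficial SAT split and ROI refinement."""

import numpy as np
import pytest

from facmri import segmentation as seg
from facmri.maps import FACMaps
from facmri.synth import build_truth


@pytest.fixture(scope="module")
def phantom_truth(small_phantom_spec):
    return build_truth(small_phantom_spec)


def _ring_ff(shape=(24, 24), r_in=6.0, r_out=10.0, high=0.95, low=0.1):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    d = np.hypot(rr - (shape[0] - 1) / 2, cc - (shape[1] - 1) / 2)
    ff = np.zeros(shape)
    ff[d <= r_out] = low
    annulus = (d <= r_out) & (d >= r_in)
    ff[annulus] = high
    return ff, annulus


class TestRegionGrowing:
    def test_annulus_recovered_exactly(self):
        ff, annulus = _ring_ff()
        rr, cc = np.nonzero(annulus)
        mask = seg.region_grow_sat(ff, (rr[0], cc[0]), 0.5)
        np.testing.assert_array_equal(mask, annulus)

    def test_low_ff_seed_rejected(self):
        ff, _ = _ring_ff()
        center = (ff.shape[0] // 2, ff.shape[1] // 2)
        with pytest.raises(ValueError, match="below the growth threshold"):
            seg.region_grow_sat(ff, center, 0.5)

    def test_disjoint_blob_not_included(self):
        ff = np.zeros((10, 20))
        ff[2:5, 2:5] = 0.95   # blob 1
        ff[2:5, 12:15] = 0.95  # blob 2, disconnected
        mask = seg.region_grow_sat(ff, (3, 3), 0.5)
        assert mask[2:5, 2:5].all()
        assert not mask[:, 10:].any()

    def test_diagonal_touch_not_connected(self):
        ff = np.zeros((4, 4))
        ff[0, 0] = ff[1, 1] = 0.95  # 8-neighbours but not 4-neighbours
        mask = seg.region_grow_sat(ff, (0, 0), 0.5)
        assert mask[0, 0] and not mask[1, 1]

    def test_idempotent_from_any_seed_inside_result(self):
        ff, annulus = _ring_ff()
        rr, cc = np.nonzero(annulus)
        first = seg.region_grow_sat(ff, (rr[0], cc[0]), 0.5)
        for i in range(0, len(rr), 17):
            again = seg.region_grow_sat(ff, (rr[i], cc[i]), 0.5)
            np.testing.assert_array_equal(first, again)

    def test_phantom_sat_dice_is_one(self, phantom_truth):
        truth_sat = phantom_truth.depot_mask("sat")
        mask = seg.region_grow_sat(
            phantom_truth.fat_fraction, phantom_truth.sat_seed(), 0.5
        )
        assert seg.dice(mask, truth_sat) == 1.0


class TestVatDelineation:
    def test_whole_image_polygon_gives_sat_complement(self):
        ff = np.full((10, 12), 0.5)
        sat = np.zeros((10, 12), bool)
        sat[0:2, :] = True
        poly = [(-0.5, -0.5), (-0.5, 11.5), (9.5, 11.5), (9.5, -0.5)]
        vat = seg.delineate_vat(poly, sat, ff)
        np.testing.assert_array_equal(vat, ~sat)

    def test_polygon_inside_sat_is_empty(self):
        ff = np.full((10, 12), 0.5)
        sat = np.ones((10, 12), bool)
        poly = [(2, 2), (2, 8), (7, 8), (7, 2)]
        vat = seg.delineate_vat(poly, sat, ff)
        assert not vat.any()

    def test_degenerate_polygon_rejected(self):
        ff = np.zeros((5, 5))
        sat = np.zeros((5, 5), bool)
        with pytest.raises(ValueError, match="degenerate"):
            seg.delineate_vat([(1, 1), (1, 1), (1, 1)], sat, ff)

    def test_phantom_cavity_polygon_recovers_cavity(self, phantom_truth):
        from facmri.synth import AIR

        sat = phantom_truth.depot_mask("sat")
        vat = seg.delineate_vat(phantom_truth.cavity_polygon(), sat, phantom_truth.fat_fraction)
        cavity = (phantom_truth.labels != AIR) & ~sat
        np.testing.assert_array_equal(vat, cavity)


class TestSatSplit:
    def _band(self, shape=(20, 16)):
        """Posterior SAT band: rows 14..17 across all columns."""
        sat = np.zeros(shape, bool)
        sat[14:18, :] = True
        return sat

    def test_straight_fascia_splits_band(self):
        sat = self._band()
        polyline = [(16.0, -1.0), (16.0, 16.0)]
        dsat, ssat = seg.split_sat_depots(sat, polyline)
        assert dsat[14].all() and dsat[15].all()
        assert ssat[16].all() and ssat[17].all()
        np.testing.assert_array_equal(dsat | ssat, sat)

    def test_polyline_on_inner_boundary_gives_all_superficial(self):
        sat = self._band()
        polyline = [(14.0, -1.0), (14.0, 16.0)]
        dsat, ssat = seg.split_sat_depots(sat, polyline)
        assert not dsat.any()
        np.testing.assert_array_equal(ssat, sat)

    def test_anterior_only_sat_gives_empty_outputs(self):
        sat = np.zeros((20, 16), bool)
        sat[2:5, :] = True  # upper (anterior) half only
        dsat, ssat = seg.split_sat_depots(sat, [(16.0, -1.0), (16.0, 16.0)])
        assert not dsat.any() and not ssat.any()

    def test_short_polyline_rejected(self):
        sat = self._band()
        with pytest.raises(ValueError, match="does not span"):
            seg.split_sat_depots(sat, [(16.0, 5.0), (16.0, 8.0)])

    def test_phantom_fascia_recovers_truth_shells(self, small_phantom_spec):
        """On the phantom, the polyline split reproduces the ground-truth
        deep/superficial shells in the posterior half."""
        from dataclasses import replace

        spec = replace(
            small_phantom_spec,
            dsat=replace(small_phantom_spec.sat, ndb=2.2),
            ssat=replace(small_phantom_spec.sat, ndb=2.6),
        )
        truth = build_truth(spec)
        sat = truth.depot_mask("sat")
        dsat, ssat = seg.split_sat_depots(sat, truth.fascia_polyline())
        lower = np.zeros_like(sat)
        lower[sat.shape[0] // 2:, :] = True
        np.testing.assert_array_equal(dsat, truth.depot_mask("dsat") & lower)
        np.testing.assert_array_equal(ssat, truth.depot_mask("ssat") & lower)


class TestRoiRefinement:
    def test_hand_computed_survivors(self):
        ff = np.array([[0.95, 0.80], [0.92, 0.95]])
        t2s = np.array([[0.025, 0.030], [0.015, 0.040]])
        roi = seg.refine_roi(np.ones((2, 2), bool), ff, t2s)
        assert roi.sum() == 2
        assert roi[0, 0] and roi[1, 1]

    def test_thresholds_are_strict(self):
        ff = np.full((3, 3), 0.9)
        t2s = np.full((3, 3), 0.025)
        roi = seg.refine_roi(np.ones((3, 3), bool), ff, t2s)
        assert not roi.any()

    def test_all_pass_returns_input_mask(self):
        mask = np.zeros((3, 3), bool)
        mask[1, :] = True
        ff = np.full((3, 3), 0.95)
        t2s = np.full((3, 3), 0.030)
        np.testing.assert_array_equal(seg.refine_roi(mask, ff, t2s), mask)

    def test_monotone_in_thresholds(self, rng):
        ff = rng.uniform(0.7, 1.0, (10, 10))
        t2s = rng.uniform(0.010, 0.040, (10, 10))
        mask = np.ones((10, 10), bool)
        loose = seg.refine_roi(mask, ff, t2s, ff_min=0.85)
        tight = seg.refine_roi(mask, ff, t2s, ff_min=0.95)
        assert not (tight & ~loose).any()

    def test_output_subset_of_input(self, rng):
        ff = rng.uniform(0.0, 1.0, (10, 10))
        t2s = rng.uniform(0.0, 0.05, (10, 10))
        mask = rng.random((10, 10)) > 0.5
        roi = seg.refine_roi(mask, ff, t2s)
        assert not (roi & ~mask).any()


class TestDepotMean:
    def _fac(self, fpufa_values):
        shape = (1, len(fpufa_values))
        fpufa = np.asarray(fpufa_values, float)[None, :]
        fmufa = np.full(shape, 0.5)
        fsfa = 1.0 - fmufa - fpufa
        return FACMaps(
            fsfa=fsfa, fmufa=fmufa, fpufa=fpufa,
            fat_fraction=np.full(shape, 0.95),
            t2star_s=np.full(shape, 0.03),
            valid=np.ones(shape, bool),
        )

    def test_homogeneous_roi(self):
        fac = self._fac([0.1, 0.1, 0.1])
        s = seg.depot_mean_fac(fac, np.ones((1, 3), bool))
        assert s.fpufa == pytest.approx(0.1)
        assert s.n_voxels == 3

    def test_two_voxel_mean(self):
        fac = self._fac([0.10, 0.20])
        s = seg.depot_mean_fac(fac, np.ones((1, 2), bool))
        assert s.fpufa == pytest.approx(0.15)

    def test_means_preserve_fraction_sum(self):
        fac = self._fac([0.05, 0.15, 0.25])
        s = seg.depot_mean_fac(fac, np.ones((1, 3), bool))
        assert s.fsfa + s.fmufa + s.fpufa == pytest.approx(1.0)

    def test_empty_roi_rejected(self):
        fac = self._fac([0.1])
        with pytest.raises(ValueError, match="no valid voxels"):
            seg.depot_mean_fac(fac, np.zeros((1, 1), bool))


class TestDepotMasks:
    def test_overlap_rejected(self):
        a = np.ones((2, 2), bool)
        with pytest.raises(ValueError, match="overlap"):
            seg.DepotMasks(sat=a, vat=a)

    def test_subset_invariant(self):
        sat = np.zeros((2, 2), bool)
        sat[0] = True
        bad = np.zeros((2, 2), bool)
        bad[1] = True
        with pytest.raises(ValueError, match="subset"):
            seg.DepotMasks(sat=sat, vat=np.zeros((2, 2), bool), dsat=bad, ssat=None)
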