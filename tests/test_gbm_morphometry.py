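"""GBM morphometry: cleanup, shape, thickness estimators, skeleton quality, filtering."""

import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate

from glomorph.gbm_morphometry import (
    FilterCriteria,
    GbmInstance,
    Skeleton,
    boundary_thickness,
    clean_instance,
    extract_instances,
    filter_instances,
    gbm_summary,
    shape_descriptors,
    skeleton_quality,
    skeleton_thickness,
    skeletonize_instance,
    smooth_contour,
)
from glomorph.gbm_morphometry import _skeleton_graph
from glomorph.mask_io import Calibration, LabeledInstance, MaskSet
from glomorph.phantom_generator import PhantomSpec, generate_phantom

CAL = Calibration(2.0, 512, 512)


def _inst(mask, iid=1, calib=CAL):
    return GbmInstance(instance_id=iid, mask=np.asarray(mask, bool), calibration=calib)


def _rect(h, w, shape=(260, 260), r0=20, c0=20):
    m = np.zeros(shape, bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


def _brute_opening(mask, footprint):
    """Opening by definition: union of footprint translates contained in the set."""
    out = np.zeros_like(mask)
    fh, fw = footprint.shape
    H, W = mask.shape
    for r in range(H - fh + 1):
        for c in range(W - fw + 1):
            sub = mask[r : r + fh, c : c + fw]
            if np.all(sub[footprint]):
                out[r : r + fh, c : c + fw] |= footprint
    return out


class TestExtractAndClean:
    def test_small_area_exclusion(self):
        insts = []
        areas = [(2000, (10, 200)), (1500, (10, 150)), (40, (5, 8))]
        ms_list = []
        for k, (_, (h, w)) in enumerate(areas):
            m = np.zeros((300, 300), bool)
            m[20 + 30 * k : 20 + 30 * k + h, 10 : 10 + w] = True
            ms_list.append(LabeledInstance(k + 1, "GBM", pixel_mask=m))
        ms = MaskSet(calibration=Calibration(2.0, 300, 300), instances=ms_list)
        got = extract_instances(ms, FilterCriteria(min_area_px2=500))
        assert len(got) == 2

    def test_no_gbm_instances_gives_empty_list(self):
        ms = MaskSet(calibration=CAL, instances=[])
        assert extract_instances(ms, FilterCriteria()) == []

    def test_opening_matches_brute_force_and_removes_speckles(self):
        from skimage.morphology import disk

        m = np.zeros((40, 130), bool)
        m[10:20, 10:110] = True  # 100x10 rectangle
        for r, c in [(3, 3), (30, 50), (5, 120), (35, 5), (25, 125)]:
            m[r, c] = True
        inst = _inst(m.copy())
        inst = clean_instance(inst, 1)
        oracle = _brute_opening(m, disk(1).astype(bool))
        assert np.array_equal(inst.mask, oracle)
        # speckles gone; rectangle preserved except the 4 disk-clipped corners
        assert not any(inst.mask[r, c] for r, c in [(3, 3), (30, 50), (5, 120), (35, 5), (25, 125)])
        assert inst.mask.sum() == 996

    def test_radius_zero_is_identity(self):
        m = _rect(10, 100)
        inst = _inst(m.copy())
        clean_instance(inst, 0)
        assert np.array_equal(inst.mask, m)

    def test_opening_idempotent(self):
        spec = PhantomSpec(nm_per_pixel=4.0, image_height=128, image_width=300, width_nm=100,
                           boundary_noise_sd_px=1.0)
        ms, _ = generate_phantom(spec, 9)
        inst = extract_instances(ms, FilterCriteria())[0]
        once = clean_instance(inst, 1).mask.copy()
        twice = clean_instance(inst, 1).mask
        assert np.array_equal(once, twice)

    def test_annihilated_instance_flagged_not_crashed(self):
        m = np.zeros((20, 20), bool)
        m[5, 5] = True
        m[8, 9] = True
        inst = _inst(m)
        clean_instance(inst, 2)
        assert "opening_annihilated" in inst.reject_reasons


class TestShapeDescriptors:
    def test_square_compactness_near_pi_over_4(self):
        d = shape_descriptors(_inst(_rect(60, 60)))
        assert d.compactness == pytest.approx(np.pi / 4, rel=0.05)

    def test_thin_rectangle_compactness(self):
        d = shape_descriptors(_inst(_rect(2, 100)))
        assert d.compactness == pytest.approx(4 * np.pi * 200 / 204**2, rel=0.10)

    def test_convex_instance_fill_rate_one(self):
        yy, xx = np.mgrid[0:200, 0:200]
        m = (yy - 100) ** 2 + (xx - 100) ** 2 <= 60**2
        d = shape_descriptors(_inst(m))
        assert d.fill_rate == pytest.approx(1.0, abs=0.02)

    def test_degenerate_instance_raises(self):
        m = np.zeros((10, 10), bool)
        m[4, 4] = True
        with pytest.raises(ValueError):
            shape_descriptors(_inst(m))


class TestSmoothContour:
    def test_zero_tolerance_is_identity(self):
        c = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0]])
        assert np.array_equal(smooth_contour(c, 0.0), c)

    def test_noisy_square_reduces_to_corners(self):
        rng = np.random.default_rng(0)
        side = np.linspace(0, 50, 60)
        top = np.column_stack([np.zeros_like(side), side])
        right = np.column_stack([side, np.full_like(side, 50.0)])
        bottom = np.column_stack([np.full_like(side, 50.0), side[::-1]])
        left = np.column_stack([side[::-1], np.zeros_like(side)])
        sq = np.vstack([top, right, bottom, left])
        noisy = sq + rng.uniform(-0.7, 0.7, sq.shape)
        noisy[0] = noisy[-1] = sq[0]
        out = smooth_contour(noisy, 2.0 / (4 * 50))
        assert len(out) <= 8  # corners (+ closure duplicate) survive
        # every dropped vertex lies within the tolerance of the output polyline
        from scipy.spatial import cKDTree

        dense = []
        for a, b in zip(out[:-1], out[1:]):
            t = np.linspace(0, 1, 50)[:, None]
            dense.append(a + t * (b - a))
        d, _ = cKDTree(np.vstack(dense)).query(noisy)
        assert d.max() <= 2.0 + 1e-6

    def test_negative_tolerance_rejected(self):
        c = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        with pytest.raises(ValueError):
            smooth_contour(c, -0.1)

    def test_phantom_ribbon_area_preserved(self):
        spec = PhantomSpec(nm_per_pixel=4.0, image_height=160, image_width=400, width_nm=160,
                           waviness_amplitude_px=12, waviness_period_px=180)
        ms, _ = generate_phantom(spec, 2)
        inst = extract_instances(ms, FilterCriteria())[0]
        from glomorph.gbm_morphometry import _traced_contours
        from shapely.geometry import Polygon

        contour = _traced_contours(inst.mask)[0]
        a0 = Polygon(contour).area
        sm = smooth_contour(contour, 0.002)
        a1 = Polygon(sm).area
        assert abs(a1 - a0) / a0 < 0.05


class TestThickness:
    def test_constant_width_ribbon_boundary(self):
        inst = _inst(_rect(10, 200))
        prof = boundary_thickness(inst)
        assert 9.0 <= prof.mean_boundary_px <= 11.0

    def test_annulus_ring_width(self):
        yy, xx = np.mgrid[0:140, 0:140]
        R = np.hypot(yy - 70, xx - 70)
        inst = _inst((R >= 50) & (R < 60), calib=Calibration(2.0, 140, 140))
        prof = boundary_thickness(inst)
        assert prof.mean_boundary_px == pytest.approx(10.0, abs=1.0)

    def test_phantom_ribbon_350nm_recovered(self):
        spec = PhantomSpec(nm_per_pixel=2.0, image_height=500, image_width=1200, width_nm=350.0)
        ms, _ = generate_phantom(spec, 42)
        inst = extract_instances(ms, FilterCriteria())[0]
        prof = boundary_thickness(inst)
        assert prof.mean_boundary_nm == pytest.approx(350.0, rel=0.10)

    def test_blob_has_no_ribbon_partition(self):
        from glomorph.gbm_morphometry import RibbonPartitionError

        yy, xx = np.mgrid[0:100, 0:100]
        m = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
        inst = _inst(m)
        with pytest.raises(RibbonPartitionError):
            boundary_thickness(inst)
        assert "no_ribbon_partition" in inst.reject_reasons

    def test_skeleton_thickness_arithmetic(self):
        inst = _inst(_rect(10, 200))  # area 2000
        skel = Skeleton(path=np.zeros((2, 2)), pixels=np.zeros((2, 2), int),
                        length_px=200.0, branch_point_count=0, is_loop=False)
        t_px, t_nm = skeleton_thickness(inst, skel)
        assert t_px == pytest.approx(10.0)
        assert t_nm == pytest.approx(20.0)

    def test_rectangle_skeleton_thickness(self):
        inst = _inst(_rect(10, 200))
        skel = skeletonize_instance(inst)
        t_px, _ = skeleton_thickness(inst, skel)
        assert t_px == pytest.approx(10.0, rel=0.15)

    def test_zero_length_rejected(self):
        inst = _inst(_rect(10, 200))
        skel = Skeleton(path=np.zeros((0, 2)), pixels=np.zeros((0, 2), int),
                        length_px=0.0, branch_point_count=0, is_loop=False)
        with pytest.raises(ValueError):
            skeleton_thickness(inst, skel)

    @pytest.mark.parametrize("width_px", [8, 20, 50])
    def test_estimator_agreement_on_constant_width(self, width_px):
        spec = PhantomSpec(nm_per_pixel=1.0, image_height=int(3 * width_px + 80),
                           image_width=int(12 * width_px + 200), width_nm=float(width_px),
                           waviness_amplitude_px=width_px / 8, waviness_period_px=200)
        ms, _ = generate_phantom(spec, width_px)
        inst = extract_instances(ms, FilterCriteria())[0]
        skel = skeletonize_instance(inst)
        t_s, _ = skeleton_thickness(inst, skel)
        prof = boundary_thickness(inst)
        assert abs(t_s - prof.mean_boundary_px) / prof.mean_boundary_px <= 0.15

    def test_scale_equivariance(self):
        spec = PhantomSpec(nm_per_pixel=4.0, image_height=120, image_width=420, width_nm=120,
                           waviness_amplitude_px=8, waviness_period_px=200)
        ms, _ = generate_phantom(spec, 21)
        inst = extract_instances(ms, FilterCriteria())[0]
        t1, _ = skeleton_thickness(inst, skeletonize_instance(inst))
        up = np.kron(inst.mask, np.ones((2, 2), bool))
        inst2 = _inst(up, calib=Calibration(2.0, up.shape[1], up.shape[0]))
        t2, _ = skeleton_thickness(inst2, skeletonize_instance(inst2))
        assert t2 / t1 == pytest.approx(2.0, rel=0.05)

    def test_rotation_robustness(self):
        spec = PhantomSpec(nm_per_pixel=4.0, image_height=150, image_width=420, width_nm=140)
        ms, _ = generate_phantom(spec, 5)
        inst = extract_instances(ms, FilterCriteria())[0]
        t0, _ = skeleton_thickness(inst, skeletonize_instance(inst))
        big = np.zeros((700, 700), bool)
        big[250 : 250 + inst.mask.shape[0], 120 : 120 + inst.mask.shape[1]] = inst.mask
        for ang in (30, 60, 90):
            rot = nd_rotate(big, ang, order=0, reshape=False)
            inst_r = _inst(rot, calib=Calibration(4.0, 700, 700))
            t_r, _ = skeleton_thickness(inst_r, skeletonize_instance(inst_r))
            assert t_r / t0 == pytest.approx(1.0, abs=0.05)


class TestSkeleton:
    def test_rectangle_skeleton_near_row_center(self):
        inst = _inst(_rect(10, 200, r0=100))
        skel = skeletonize_instance(inst)
        rows = skel.path[:, 0] + inst.origin[0]
        assert np.all(np.abs(rows - (100 + 4.5)) <= 5)

    def test_one_pixel_line_is_its_own_skeleton(self):
        m = np.zeros((10, 50), bool)
        m[5, 5:45] = True
        inst = _inst(m)
        skel = skeletonize_instance(inst)
        assert set(map(tuple, skel.pixels)) == set(map(tuple, np.argwhere(m)))

    def test_plus_shape_has_one_branch_neighborhood(self):
        m = np.zeros((80, 80), bool)
        m[35:45, 10:70] = True
        m[10:70, 35:45] = True
        skel = skeletonize_instance(_inst(m))
        assert skel.branch_point_count >= 1
        # branch pixels form exactly one connected cluster
        g = _skeleton_graph(set(map(tuple, skel.pixels)))
        bp = {p for p, ns in g.items() if len(ns) > 2}
        clusters = 0
        seen = set()
        for p in bp:
            if p in seen:
                continue
            clusters += 1
            stack = [p]
            while stack:
                q = stack.pop()
                seen.add(q)
                stack.extend(r for r in g[q] if r in bp and r not in seen)
        assert clusters == 1

    def test_skeleton_subset_of_instance(self):
        spec = PhantomSpec(nm_per_pixel=4.0, image_height=128, image_width=360, width_nm=120,
                           waviness_amplitude_px=10, waviness_period_px=150)
        ms, _ = generate_phantom(spec, 8)
        inst = extract_instances(ms, FilterCriteria())[0]
        skel = skeletonize_instance(inst)
        assert all(inst.mask[r, c] for r, c in skel.pixels)

    def test_skeleton_length_bounded_by_perimeter(self):
        spec = PhantomSpec(nm_per_pixel=4.0, image_height=128, image_width=360, width_nm=120)
        ms, _ = generate_phantom(spec, 8)
        inst = extract_instances(ms, FilterCriteria())[0]
        d = shape_descriptors(inst)
        skel = skeletonize_instance(inst)
        assert skel.length_px <= d.perimeter_px


class TestSkeletonQuality:
    def test_straight_line_scores(self):
        m = np.zeros((20, 200), bool)
        m[10, 5:195] = True
        skel = skeletonize_instance(_inst(m))
        k_hat, b_hat, sd_k, _ = skeleton_quality(skel)
        assert b_hat == 0
        assert k_hat < 0.02
        assert sd_k < 0.01

    def test_circular_arc_curvature_matches_radius(self):
        r = 40
        th = np.linspace(0, 1.5 * np.pi, 3000)
        pts = np.column_stack([np.round(100 + r * np.sin(th)), np.round(100 + r * np.cos(th))])
        keep = [0]
        for i in range(1, len(pts)):
            if not np.array_equal(pts[i], pts[keep[-1]]):
                keep.append(i)
        path = pts[keep].astype(float)
        skel = Skeleton(path=path, pixels=path.astype(int), length_px=1.5 * np.pi * r,
                        branch_point_count=0, is_loop=False)
        skeleton_quality(skel)
        assert np.abs(skel.curvature).mean() == pytest.approx(1 / r, rel=0.20)

    def test_branch_score_arithmetic(self):
        path = np.column_stack([np.full(101, 5.0), np.arange(101.0)])
        skel = Skeleton(path=path, pixels=path.astype(int), length_px=100.0,
                        branch_point_count=1, is_loop=False)
        _, b_hat, _, _ = skeleton_quality(skel)
        assert b_hat == pytest.approx(0.01)


class TestFiltering:
    def _described(self, mask, iid=1):
        inst = _inst(mask, iid)
        shape_descriptors(inst)
        skel = skeletonize_instance(inst)
        skeleton_quality(skel)
        return inst

    def test_permissive_criteria_accept_all(self):
        insts = [self._described(_rect(10, 200), 1), self._described(_rect(40, 40), 2)]
        crit = FilterCriteria(min_area_px2=0, compactness_lo=0, compactness_hi=np.inf,
                              min_fill_rate=0, max_norm_curvature=np.inf, max_norm_branch=np.inf)
        assert len(filter_instances(insts, crit)) == 2

    def test_compact_disk_rejected_with_reason(self):
        yy, xx = np.mgrid[0:100, 0:100]
        disk_mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
        inst = self._described(disk_mask)
        filter_instances([inst], FilterCriteria(compactness_hi=0.3))
        assert not inst.accepted
        assert "compactness" in inst.reject_reasons

    def test_filtering_monotone_in_each_criterion(self):
        rng = np.random.default_rng(4)
        insts = []
        for k in range(6):
            spec = PhantomSpec(nm_per_pixel=4.0, image_height=128, image_width=360,
                               width_nm=float(rng.uniform(80, 200)),
                               waviness_amplitude_px=float(rng.uniform(0, 14)),
                               waviness_period_px=180)
            ms, _ = generate_phantom(spec, k)
            inst = extract_instances(ms, FilterCriteria())[0]
            inst.instance_id = k
            insts.append(self._described(inst.mask, k))
        base = FilterCriteria(compactness_hi=0.2, min_fill_rate=0.2, max_norm_curvature=0.05)
        n_base = len(filter_instances(insts, base))
        for relaxed in (
            FilterCriteria(compactness_hi=0.5, min_fill_rate=0.2, max_norm_curvature=0.05),
            FilterCriteria(compactness_hi=0.2, min_fill_rate=0.0, max_norm_curvature=0.05),
            FilterCriteria(compactness_hi=0.2, min_fill_rate=0.2, max_norm_curvature=1.0),
        ):
            assert len(filter_instances(insts, relaxed)) >= n_base


class TestSummary:
    def _measured(self, width_nm, seed, npp=2.0):
        spec = PhantomSpec(nm_per_pixel=npp, image_height=300, image_width=900, width_nm=width_nm)
        ms, _ = generate_phantom(spec, seed)
        inst = extract_instances(ms, FilterCriteria())[0]
        skel = skeletonize_instance(inst)
        skeleton_thickness(inst, skel)
        boundary_thickness(inst)
        inst.accepted = True
        return inst

    def test_single_ribbon_mean(self):
        inst = self._measured(300, 1)
        rec = gbm_summary([inst], CAL)
        assert rec["thickness_mean_nm"] == pytest.approx(300, rel=0.05)

    def test_two_ribbon_pooling(self):
        a, b = self._measured(200, 1), self._measured(400, 2)
        rec = gbm_summary([a, b], CAL)
        assert rec["thickness_mean_nm"] == pytest.approx(300, rel=0.05)

    def test_zero_accepted_explicit_record(self):
        rec = gbm_summary([], CAL)
        assert rec["gbm_measured"] is False
        assert rec["gbm_count"] == 0
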