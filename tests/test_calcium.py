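import numpy as np
import pytest

import corochar as cc
from corochar.calcium import (
    CacParams,
    CalciumLesion,
    analyze_calcium,
    detect_candidates,
    filter_artifacts,
    grow_lesions,
    patient_threshold,
    project_to_centerline,
    score,
    search_volume,
    _split_lesions,
)
from corochar.centerline import CenterlineTree, branch_from_points
from corochar.volume import ImageVolume, LabelMap


def _flat(shape=(10, 10, 10), value=0.0, spacing=(0.5, 0.5, 0.5)):
    return ImageVolume(np.full(shape, float(value)), spacing)


def _mask(shape=(10, 10, 10), spacing=(0.5, 0.5, 0.5), box=None):
    m = np.zeros(shape, np.uint8)
    if box:
        m[box] = 1
    return LabelMap(m, spacing)


class TestPatientThreshold:
    def test_constant_aorta(self):
        img = _flat(value=450.0)
        assert patient_threshold(img, _mask(box=np.s_[2:6, 2:6, 2:6])) == 450.0

    def test_printed_formula(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(450.0, 20.0, 4096)
        vals = (vals - vals.mean()) / vals.std() * 20.0 + 450.0  # exact mu/sd
        img = ImageVolume(vals.reshape(16, 16, 16), (0.5,) * 3)
        ao = LabelMap(np.ones((16, 16, 16), np.uint8), (0.5,) * 3)
        assert patient_threshold(img, ao, 2.5) == pytest.approx(500.0, abs=1e-6)

    def test_zero_k_gives_mean(self):
        img = _flat(value=430.0)
        assert patient_threshold(img, _mask(box=np.s_[1:4, 1:4, 1:4]), 0.0) == 430.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            patient_threshold(_flat(), _mask())


class TestCandidates:
    def test_all_below_threshold_empty(self):
        img = _flat(value=100.0)
        cor = _mask(box=np.s_[2:8, 2:8, 2:8])
        assert not detect_candidates(img, cor, 500.0).any()

    def test_two_separated_lesions_two_components(self):
        img = _flat(value=100.0)
        img.data[2, 2, 2] = 900.0
        img.data[7, 7, 7] = 900.0
        cor = _mask(box=np.s_[1:9, 1:9, 1:9])
        cand = detect_candidates(img, cor, 500.0, 0.0)
        lesions = _split_lesions(cand, img)
        assert len(lesions) == 2

    def test_lowering_threshold_never_shrinks(self):
        rng = np.random.default_rng(1)
        img = ImageVolume(rng.normal(400, 100, (10, 10, 10)), (0.5,) * 3)
        cor = _mask(box=np.s_[1:9, 1:9, 1:9])
        hi = detect_candidates(img, cor, 550.0)
        lo = detect_candidates(img, cor, 450.0)
        assert np.all(lo[hi])  # hi subset of lo

    def test_phantom_lesion_core_detected(self, lesion_phantom):
        image, coronary, aorta, _ = lesion_phantom
        theta = patient_threshold(image, aorta)
        cand = detect_candidates(image, coronary, theta)
        assert cand.sum() > 0


class TestGrowth:
    def test_fixpoint_at_seed_when_gate_high(self):
        img = _flat(value=100.0)
        img.data[5, 5, 5] = 900.0
        cor = _mask(box=np.s_[2:8, 2:8, 2:8])
        cand = np.zeros((10, 10, 10), bool)
        cand[5, 5, 5] = True
        grown = grow_lesions(img, cand, cor, 99.9)
        assert np.array_equal(grown, cand)

    def test_growth_is_superset(self, lesion_phantom):
        image, coronary, aorta, _ = lesion_phantom
        theta = patient_threshold(image, aorta)
        cand = detect_candidates(image, coronary, theta)
        grown = grow_lesions(image, cand, coronary)
        assert np.all(grown[cand])

    def test_fixpoint_equals_brute_force_closure(self):
        rng = np.random.default_rng(2)
        img = ImageVolume(rng.normal(100, 50, (10, 10, 10)), (1.0,) * 3)
        cor = _mask((10, 10, 10), (1.0,) * 3, np.s_[3:8, 3:8, 3:8])
        cand = np.zeros((10, 10, 10), bool)
        cand[5, 5, 5] = True
        grown = grow_lesions(img, cand, cor, 80.0, 1.0)

        gate = np.percentile(img.data[cor.data > 0], 80.0)
        allowed = (img.data > gate) & search_volume(cor, 1.0)
        cur = cand.copy()
        while True:  # brute force: repeat until no change
            nxt = cur.copy()
            for p in np.argwhere(cur):
                lo = np.maximum(p - 1, 0)
                hi = np.minimum(p + 2, 10)
                sl = tuple(slice(a, b) for a, b in zip(lo, hi))
                nxt[sl] |= allowed[sl]
            if np.array_equal(nxt, cur):
                break
            cur = nxt
        assert np.array_equal(grown, cur)


class TestArtifactFilter:
    def test_single_voxel_removed_at_04mm(self):
        img = _flat(spacing=(0.4, 0.4, 0.4))
        les = CalciumLesion(voxels=np.array([[5, 5, 5]]), volume_mm3=0.064,
                            mean_hu=700.0)
        assert filter_artifacts([les], img) == []

    def test_3x3_inplane_blob_kept(self):
        img = _flat(spacing=(0.4, 0.4, 0.4))
        vox = np.array([[x, y, 5] for x in range(3, 6) for y in range(3, 6)])
        les = CalciumLesion(voxels=vox, volume_mm3=9 * 0.064, mean_hu=700.0)
        assert len(filter_artifacts([les], img)) == 1  # 1.44 mm^2 >= 1 mm^2

    def test_empty_input(self):
        assert filter_artifacts([], _flat()) == []

    def test_volume_mode(self):
        img = _flat(spacing=(0.4, 0.4, 0.4))
        vox = np.array([[x, y, 5] for x in range(3, 6) for y in range(3, 6)])
        les = CalciumLesion(voxels=vox, volume_mm3=9 * 0.064, mean_hu=700.0)
        # 0.576 mm^3 < 1 mm^3 in the volumetric reading
        assert filter_artifacts([les], img, area_mode="volume") == []


class TestProjection:
    def _straight_tree(self):
        pts = np.column_stack([np.linspace(0, 60, 121), np.zeros(121), np.zeros(121)])
        br = branch_from_points(pts)
        return CenterlineTree(ostium=np.zeros(3), branches=[br])

    def test_spherical_lesion_geometry(self):
        tree = self._straight_tree()
        img = _flat((160, 20, 20), spacing=(0.4, 0.4, 0.4))
        img.origin = np.array([0.0, -4.0, -4.0])
        # sphere of diameter 5 mm centered at abscissa 20 mm
        idx = []
        for i in range(160):
            for j in range(20):
                for k in range(20):
                    p = img.index_to_world(np.array([i, j, k]))
                    if np.linalg.norm(p - [20.0, 0.0, 0.0]) <= 2.5:
                        idx.append([i, j, k])
        les = CalciumLesion(voxels=np.array(idx), volume_mm3=1.0, mean_hu=700.0)
        project_to_centerline(les, tree, img)
        assert les.min_abscissa_mm == pytest.approx(17.5, abs=0.5)
        assert les.extent_mm == pytest.approx(5.0, abs=1.0)

    def test_single_point_lesion_zero_extent(self):
        tree = self._straight_tree()
        img = _flat((160, 20, 20), spacing=(0.4, 0.4, 0.4))
        img.origin = np.array([0.0, -4.0, -4.0])
        les = CalciumLesion(voxels=np.array([[50, 10, 10]]), volume_mm3=0.1,
                            mean_hu=700.0)
        project_to_centerline(les, tree, img)
        assert les.extent_mm == pytest.approx(0.0, abs=0.6)

    def test_zone_from_min_abscissa_point(self):
        tree = self._straight_tree()
        img = _flat((160, 20, 20), spacing=(0.4, 0.4, 0.4))
        img.origin = np.array([0.0, -4.0, -4.0])
        les = CalciumLesion(voxels=np.array([[30, 10, 10]]), volume_mm3=0.1,
                            mean_hu=700.0)  # abscissa 12 mm -> g = 0.2
        project_to_centerline(les, tree, img)
        assert les.zone == "proximal"


class TestScore:
    def test_no_lesions(self):
        rep = score([], 2000.0)
        assert rep.vs_total_mm3 == 0.0
        assert rep.ppv_percent == 0.0

    def test_ppv_arithmetic(self):
        les = CalciumLesion(voxels=np.zeros((1, 3), int), volume_mm3=50.0,
                            mean_hu=700.0, min_abscissa_mm=10.0,
                            max_abscissa_mm=14.0, zone="proximal")
        rep = score([les], 2000.0)
        assert rep.ppv_percent == pytest.approx(2.5)

    def test_zone_vs_sums_to_total(self):
        mk = lambda zone, v: CalciumLesion(
            voxels=np.zeros((1, 3), int), volume_mm3=v, mean_hu=700.0,
            min_abscissa_mm=1.0, max_abscissa_mm=2.0, zone=zone)
        rep = score([mk("proximal", 30.0), mk("distal", 20.0)], 1000.0)
        assert sum(rep.vs_by_zone.values()) == pytest.approx(rep.vs_total_mm3)
        assert rep.vs_total_mm3 == pytest.approx(50.0)

    def test_zero_vessel_volume_rejected(self):
        with pytest.raises(ValueError):
            score([], 0.0)


def test_end_to_end_recovery(lesion_phantom, lesion_tree):
    image, coronary, aorta, truth = lesion_phantom
    rep = analyze_calcium(image, coronary, aorta, lesion_tree)
    t = truth.lesions[0]
    main = max(rep.lesions, key=lambda l: l.volume_mm3)
    assert abs(main.volume_mm3 / t["volume_mm3"] - 1) <= 0.20
    assert abs(main.extent_mm - t["extent_mm"]) <= 1.5
    assert abs(main.min_abscissa_mm - t["min_abscissa_mm"]) <= 1.5
    assert main.zone == "proximal"
    # determinism of the full stage
    rep2 = analyze_calcium(image, coronary, aorta, lesion_tree)
    assert rep2.vs_total_mm3 == rep.vs_total_mm3
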