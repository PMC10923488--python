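"""Occlusion saliency, ensemble averaging, and coverage thresholds."""

import numpy as np
import pytest

from gazesal.maps import AttentionMap, FaceMask, IntensityGrid
from gazesal.saliency import (OcclusionConfig, PrototypeClassifier, SaliencyMap,
                              UnreliableSaliencyError, coverage_threshold,
                              ensemble_saliency, match_coverage,
                              occlusion_saliency, occlusion_offsets)


class CountingClassifier:
    """Constant-output classifier that counts predict calls."""

    labels = ("a", "b")

    def __init__(self):
        self.calls = 0

    def predict(self, image):
        self.calls += 1
        return np.array([0.6, 0.4])


class RegionMeanClassifier:
    """p(target) is a monotone function of mean intensity inside region R."""

    labels = ("target", "other")

    def __init__(self, region_mask):
        self.region = region_mask

    def predict(self, image):
        m = float(np.asarray(image)[self.region].mean())
        p = 1.0 / (1.0 + np.exp(-4.0 * m))
        return np.array([p, 1.0 - p])


def brute_force_occlusion(image, clf, target, cfg):
    """Independent exhaustive implementation: for every pixel, gather the
    drops of all boxes covering it (fresh image copy and prediction per
    box) and average them with plain sequential summation."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    ti = list(clf.labels).index(target)
    p0 = float(clf.predict(img.copy())[ti])
    drops = [[[] for _ in range(w)] for _ in range(h)]
    for y0 in range(0, h - cfg.box + 1, cfg.stride):
        for x0 in range(0, w - cfg.box + 1, cfg.stride):
            occluded = img.copy()
            occluded[y0:y0 + cfg.box, x0:x0 + cfg.box] = cfg.fill_value
            drop = max(p0 - float(clf.predict(occluded)[ti]), 0.0)
            for y in range(y0, y0 + cfg.box):
                for x in range(x0, x0 + cfg.box):
                    drops[y][x].append(drop)
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            if drops[y][x]:
                out[y, x] = sum(drops[y][x]) / len(drops[y][x])
    return out


class TestOcclusionSaliency:
    def test_constant_classifier_gives_zero_map(self):
        clf = CountingClassifier()
        sal = occlusion_saliency(np.random.default_rng(0).random((40, 40)), clf,
                                 "a", OcclusionConfig(box=20, stride=10))
        assert not sal.values.any()

    def test_40x40_box20_stride10_performs_exactly_nine_occlusions(self):
        clf = CountingClassifier()
        occlusion_saliency(np.ones((40, 40)), clf, "a",
                           OcclusionConfig(box=20, stride=10))
        assert clf.calls == 1 + 9  # baseline + 3 offsets per axis

    def test_offsets_only_fully_inside(self):
        assert list(occlusion_offsets(40, 20, 10)) == [0, 10, 20]
        assert list(occlusion_offsets(45, 20, 10)) == [0, 10, 20]  # 25 would clip
        assert list(occlusion_offsets(10, 20, 10)) == []

    def test_saliency_confined_to_boxes_intersecting_sensitive_region(self):
        region = np.zeros((60, 60), dtype=bool)
        region[10:25, 30:45] = True
        clf = RegionMeanClassifier(region)
        img = np.ones((60, 60))
        cfg = OcclusionConfig(box=10, stride=5)
        sal = occlusion_saliency(img, clf, "target", cfg)
        # reachable pixels: any box overlapping R covers at most R dilated by box-1
        reach = np.zeros((60, 60), dtype=bool)
        reach[max(0, 10 - 9):25 + 9, max(0, 30 - 9):45 + 9] = True
        assert sal.values[~reach].max() == 0.0
        assert sal.values[region].max() > 0.0

    def test_matches_brute_force_exactly(self, rng):
        cfg = OcclusionConfig(box=16, stride=8)
        region = np.zeros((48, 48), dtype=bool)
        region[8:28, 12:36] = True
        clf = RegionMeanClassifier(region)
        for _ in range(3):
            img = rng.random((48, 48))
            fast = occlusion_saliency(img, clf, "target", cfg).values
            slow = brute_force_occlusion(img, clf, "target", cfg)
            assert (fast == slow).all()

    def test_near_zero_target_probability_refused(self):
        class Hopeless:
            labels = ("t", "u")

            def predict(self, image):
                return np.array([5e-5, 1 - 5e-5])

        with pytest.raises(UnreliableSaliencyError):
            occlusion_saliency(np.ones((30, 30)), Hopeless(), "t",
                               OcclusionConfig(box=10, stride=10))

    def test_low_target_probability_warns(self):
        class Shaky:
            labels = ("t", "u")

            def predict(self, image):
                return np.array([5e-3, 1 - 5e-3])

        with pytest.warns(UserWarning, match="low"):
            occlusion_saliency(np.ones((20, 20)), Shaky(), "t",
                               OcclusionConfig(box=10, stride=10))


def smap(values, image="img1", target="t", box=2, stride=1):
    return SaliencyMap(IntensityGrid(np.asarray(values, dtype=float)),
                       image_id=image, target_label=target, box=box, stride=stride)


class TestEnsemble:
    def test_mean_of_identical_maps_is_the_map(self):
        s = smap([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(ensemble_saliency([s, s]).values, s.values)

    def test_zero_member_halves(self):
        s = smap([[2.0, 4.0], [6.0, 8.0]])
        z = smap(np.zeros((2, 2)))
        np.testing.assert_allclose(ensemble_saliency([s, z]).values, s.values / 2)

    def test_elementwise_mean_of_five_members(self, rng):
        grids = [rng.random((2, 2)) for _ in range(5)]
        expected = sum(grids) / 5.0
        out = ensemble_saliency([smap(g) for g in grids])
        np.testing.assert_allclose(out.values, expected, rtol=1e-15)

    def test_permutation_invariant(self, rng):
        maps = [smap(rng.random((3, 3))) for _ in range(4)]
        a = ensemble_saliency(maps).values
        b = ensemble_saliency(maps[::-1]).values
        np.testing.assert_allclose(a, b, rtol=1e-15)

    def test_mismatched_target_rejected(self):
        with pytest.raises(ValueError):
            ensemble_saliency([smap(np.ones((2, 2)), target="a"),
                               smap(np.ones((2, 2)), target="b")])


class TestCoverageThreshold:
    def test_sorting_oracle_four_of_nine(self, full_mask):
        v = np.arange(1.0, 10.0).reshape(3, 3)
        out = coverage_threshold(IntensityGrid(v), full_mask((3, 3)), 4 / 9)
        kept = out.values[out.values > 0]
        assert sorted(kept) == [6.0, 7.0, 8.0, 9.0]

    def test_fixed_point_for_already_sparse_map(self, full_mask, rng):
        v = rng.random((10, 10))
        v[v < 0.8] = 0.0
        frac = np.count_nonzero(v) / 100
        out = coverage_threshold(IntensityGrid(v), full_mask((10, 10)), frac)
        np.testing.assert_array_equal(out.values, v)

    def test_seven_percent_of_large_mask(self, rng):
        mask = FaceMask(np.ones((100, 100), dtype=bool))
        v = rng.random((100, 100))
        out = coverage_threshold(IntensityGrid(v), mask, 0.07)
        assert np.count_nonzero(out.values) == 700

    def test_outside_mask_zeroed(self, rng):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        out = coverage_threshold(IntensityGrid(rng.random((10, 10)) + 0.1),
                                 FaceMask(mask), 0.5)
        assert not out.values[~mask].any()

    def test_achieved_count_non_increasing_in_cutoff(self, rng):
        # as target fraction decreases, retained count must not grow
        mask = FaceMask(np.ones((20, 20), dtype=bool))
        v = IntensityGrid(rng.random((20, 20)))
        counts = [np.count_nonzero(coverage_threshold(v, mask, f).values)
                  for f in (0.9, 0.6, 0.3, 0.1, 0.02)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_tied_values_prefer_closest_then_sparser(self):
        mask = FaceMask(np.ones((1, 6), dtype=bool))
        v = IntensityGrid(np.array([[1.0, 2.0, 2.0, 2.0, 3.0, 4.0]]))
        # target 2: keeping ties gives 5, dropping gives 2 -> drop (closer)
        out = coverage_threshold(v, mask, 2 / 6)
        assert np.count_nonzero(out.values) == 2
        # target 4: keeping ties gives 5, dropping gives 2 -> keep (closer)
        out = coverage_threshold(v, mask, 4 / 6)
        assert np.count_nonzero(out.values) == 5

    def test_all_zero_in_mask_rejected(self, full_mask):
        with pytest.raises(ValueError):
            coverage_threshold(IntensityGrid(np.zeros((3, 3))), full_mask((3, 3)), 0.5)


class TestMatchCoverage:
    def test_exact_rank_selection_against_distinct_reference(self, rng):
        mask = FaceMask(np.ones((12, 12), dtype=bool))
        ref_v = np.zeros((12, 12))
        ref_v.flat[rng.choice(144, 30, replace=False)] = 1.0
        ref = AttentionMap(IntensityGrid(ref_v), "GROUP_AVG", "clinician",
                           "img1", "thresholded_low")
        sal = smap(rng.random((12, 12)) + 0.01)
        out = match_coverage(sal, ref, mask)
        assert np.count_nonzero(out.values) == 30

    def test_reference_fully_covered_leaves_saliency_unthresholded(self, rng):
        mask = FaceMask(np.ones((8, 8), dtype=bool))
        ref = AttentionMap(IntensityGrid(np.ones((8, 8))), "GROUP_AVG",
                           "clinician", "img1", "thresholded_low")
        v = rng.random((8, 8)) + 0.01
        out = match_coverage(smap(v), ref, mask)
        np.testing.assert_array_equal(out.values, v)

    def test_matched_counts_within_one_percent_of_mask_area(self, rng):
        h = w = 60
        yy, xx = np.mgrid[0:h, 0:w]
        mask = FaceMask(((xx - 30) ** 2 + (yy - 30) ** 2) <= 28 ** 2)
        for _ in range(20):
            ref_v = rng.random((h, w))
            ref_v[ref_v < rng.uniform(0.3, 0.95)] = 0.0
            if not ref_v[mask.mask].any():
                continue
            ref = AttentionMap(IntensityGrid(ref_v), "GROUP_AVG", "clinician",
                               "img1", "thresholded_low")
            out = match_coverage(smap(rng.random((h, w))), ref, mask)
            n_ref = np.count_nonzero(ref_v[mask.mask])
            n_out = np.count_nonzero(out.values[mask.mask])
            assert abs(n_out - n_ref) <= 0.01 * mask.area


class TestPrototypeClassifier:
    def test_probabilities_normalised_and_deterministic(self, rng):
        protos = {"a": rng.random((16, 16)), "b": rng.random((16, 16))}
        clf = PrototypeClassifier(["a", "b"], protos)
        img = rng.random((16, 16))
        p1, p2 = clf.predict(img), clf.predict(img)
        assert abs(p1.sum() - 1.0) < 1e-6 and (p1 >= 0).all()
        np.testing.assert_array_equal(p1, p2)

    def test_own_prototype_is_most_probable(self, rng):
        protos = {"a": rng.random((8, 8)), "b": rng.random((8, 8))}
        clf = PrototypeClassifier(["a", "b"], protos)
        assert clf.predict(protos["a"])[0] > clf.predict(protos["a"])[1]
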