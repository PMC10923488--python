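"""Attention-map preprocessing: rendering, averaging, subtraction,
smoothing, thresholding, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazesal.maps import (AttentionMap, FaceMask, FixationEvent, IntensityGrid,
                          ThresholdSpec, apply_noise_threshold, average_maps,
                          common_attention, render_from_fixations, smooth,
                          subtract_common)
from conftest import amap


def fix(x, y, dur, onset=0.0, pid="p1", img="img1"):
    return FixationEvent(participant_id=pid, image_id=img, x=x, y=y,
                         onset_ms=onset, duration_ms=dur)


class TestRenderFromFixations:
    def test_empty_stream_gives_zero_map(self):
        m = render_from_fixations([], (32, 48))
        assert m.values.shape == (32, 48)
        assert not m.values.any()
        assert m.stage == "raw"

    def test_single_fixation_peaks_at_its_pixel_with_bounded_support(self):
        m = render_from_fixations([fix(40, 30, 1000.0)], (80, 80), radius=25)
        peak = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert peak == (30, 40)
        yy, xx = np.nonzero(m.values)
        assert ((yy - 30) ** 2 + (xx - 40) ** 2 <= 25 ** 2).all()

    def test_deposits_are_linear_in_duration(self):
        # two fixations at one pixel (200 + 300 ms) = 500/200 x the 200 ms map
        one = render_from_fixations([fix(10, 10, 200.0)], (30, 30))
        two = render_from_fixations([fix(10, 10, 200.0), fix(10, 10, 300.0, onset=300)],
                                    (30, 30))
        np.testing.assert_allclose(two.values, one.values * (500.0 / 200.0), rtol=1e-12)

    def test_mass_proportional_to_total_duration_away_from_border(self):
        a = render_from_fixations([fix(40, 40, 500.0)], (90, 90))
        b = render_from_fixations([fix(40, 40, 250.0), fix(50, 45, 250.0, onset=400)],
                                  (90, 90))
        np.testing.assert_allclose(a.values.sum(), b.values.sum(), rtol=1e-12)

    def test_out_of_grid_fixation_is_rejected_with_coordinates(self):
        with pytest.raises(ValueError, match="x=99"):
            render_from_fixations([fix(99, 5, 100.0)], (20, 20))

    def test_mixed_participants_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            render_from_fixations([fix(5, 5, 100.0, pid="a"),
                                   fix(5, 5, 100.0, pid="b")], (20, 20))

    def test_metadata_carried_from_fixations(self):
        m = render_from_fixations([fix(5, 5, 100.0, pid="p7", img="imgX")], (20, 20))
        assert (m.participant_id, m.image_id) == ("p7", "imgX")


class TestAveraging:
    def test_average_of_identical_maps_is_the_map(self):
        m = amap([[1.0, 2.0], [3.0, 4.0]])
        avg = average_maps([m, m, m])
        np.testing.assert_array_equal(avg.values, m.values)
        assert avg.participant_id == "GROUP_AVG"

    def test_average_with_zero_halves(self):
        m = amap([[2.0, 4.0], [6.0, 8.0]])
        z = amap(np.zeros((2, 2)))
        np.testing.assert_allclose(average_maps([m, z]).values, m.values / 2)

    def test_elementwise_mean_matches_direct_summation(self, rng):
        grids = [rng.random((2, 2)) for _ in range(3)]
        expected = (grids[0] + grids[1] + grids[2]) / 3.0  # independent summation
        avg = average_maps([amap(g) for g in grids])
        np.testing.assert_allclose(avg.values, expected, rtol=1e-15)

    def test_shape_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            average_maps([amap(np.ones((2, 2))), amap(np.ones((3, 3)))])
        with pytest.raises(ValueError):
            average_maps([])

    def test_common_attention_spans_images(self, rng):
        ms = [amap(rng.random((3, 3)), participant=p, image=i)
              for p in ("a", "b") for i in ("i1", "i2")]
        c = common_attention(ms)
        expected = sum(m.values for m in ms) / 4.0
        np.testing.assert_allclose(c.values, expected, rtol=1e-15)
        assert c.image_id == "COMMON"

    def test_common_attention_of_single_map_is_that_map(self):
        m = amap([[1.0, 5.0], [0.0, 2.0]])
        np.testing.assert_array_equal(common_attention([m]).values, m.values)


class TestSubtractCommon:
    def test_self_subtraction_is_zero(self):
        m = amap([[1.0, 2.0], [3.0, 4.0]])
        assert not subtract_common(m, m).values.any()

    def test_zero_map_stays_zero_by_clipping(self):
        z = amap(np.zeros((2, 2)))
        c = amap([[1.0, 1.0], [1.0, 1.0]])
        assert not subtract_common(z, c).values.any()

    def test_elementwise_difference_with_clipping(self):
        m = amap([[5.0, 1.0], [4.0, 3.0]])
        c = amap([[2.0, 2.0], [2.0, 2.0]])
        np.testing.assert_array_equal(subtract_common(m, c).values,
                                      [[3.0, 0.0], [2.0, 1.0]])

    def test_group_mismatch_rejected(self):
        m = amap(np.ones((2, 2)), group="clinician")
        c = amap(np.ones((2, 2)), group="nonclinician")
        with pytest.raises(ValueError, match="group"):
            subtract_common(m, c)

    def test_stage_advances(self):
        out = subtract_common(amap(np.ones((2, 2))), amap(np.zeros((2, 2))))
        assert out.stage == "common_subtracted"


class TestSmooth:
    def test_kernel_one_is_identity(self, rng):
        m = amap(rng.random((5, 7)))
        np.testing.assert_array_equal(smooth(m, 1).values, m.values)

    def test_constant_map_unchanged(self):
        m = amap(np.full((6, 6), 3.5))
        np.testing.assert_allclose(smooth(m, 3).values, m.values, rtol=1e-12)

    def test_interior_value_is_window_mean_rescaled(self, rng):
        g = rng.random((3, 3))
        sm = smooth(amap(g), 3)
        # independent oracle: shrink-to-valid window means, then rescale to max
        raw = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                raw[i, j] = g[max(0, i - 1):i + 2, max(0, j - 1):j + 2].mean()
        expected = raw * (g.max() / raw.max())
        np.testing.assert_allclose(sm.values, expected, rtol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            smooth(amap(np.ones((4, 4))), 4)


class TestNoiseThreshold:
    def test_zero_cutoff_is_identity(self, rng):
        m = amap(rng.random((4, 4)))
        out = apply_noise_threshold(m, ThresholdSpec("absolute", 0.0))
        np.testing.assert_array_equal(out.values, m.values)

    def test_cutoff_above_max_zeroes_everything(self):
        m = amap(np.arange(9.0).reshape(3, 3))
        out = apply_noise_threshold(m, ThresholdSpec("absolute", 100.0))
        assert not out.values.any()

    def test_counting_oracle_one_to_nine(self):
        m = amap(np.arange(1.0, 10.0).reshape(3, 3))
        out = apply_noise_threshold(m, ThresholdSpec("absolute", 5.0))
        assert np.count_nonzero(out.values) == 5
        assert set(out.values[out.values > 0]) == {5.0, 6.0, 7.0, 8.0, 9.0}

    def test_fraction_of_max_mode(self):
        m = amap([[1.0, 2.0], [3.0, 4.0]])
        out = apply_noise_threshold(m, ThresholdSpec("fraction_of_max", 0.5))
        np.testing.assert_array_equal(out.values, [[0.0, 2.0], [3.0, 4.0]])

    def test_coverage_fraction_requires_mask(self):
        m = amap(np.ones((4, 4)))
        with pytest.raises(ValueError, match="[Mm]ask"):
            apply_noise_threshold(m, ThresholdSpec("coverage_fraction", 0.5))

    def test_nonzero_count_monotone_in_cutoff(self, rng):
        m = amap(rng.random((10, 10)))
        counts = [np.count_nonzero(
            apply_noise_threshold(m, ThresholdSpec("absolute", t)).values)
            for t in np.linspace(0, 1, 17)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_stage_cannot_regress(self):
        m = amap(np.ones((2, 2)), stage="thresholded_low")
        with pytest.raises(ValueError, match="regress"):
            m.advanced(m.values, "raw")


class TestInvariants:
    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_chain_preserves_shape_and_nonnegativity(self, seed):
        rng = np.random.default_rng(seed)
        ms = [amap(rng.random((6, 6)), participant=f"p{i}") for i in range(3)]
        c = common_attention(ms)
        out = apply_noise_threshold(
            smooth(average_maps([subtract_common(m, c) for m in ms]), 3),
            ThresholdSpec("fraction_of_max", 0.3))
        assert out.values.shape == (6, 6)
        assert (out.values >= 0).all()

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_subtraction_commutes_with_averaging_when_nothing_clips(self, seed):
        rng = np.random.default_rng(seed)
        ms = [amap(rng.random((5, 5)) + 1.0, participant=f"p{i}") for i in range(4)]
        floor = np.min([m.values for m in ms], axis=0)
        c = amap(floor * rng.random((5, 5)))  # never exceeds any map
        via_avg = subtract_common(average_maps(ms), c)
        via_members = average_maps([subtract_common(m, c) for m in ms])
        np.testing.assert_allclose(via_avg.values, via_members.values,
                                   rtol=1e-12, atol=1e-12)

    def test_negative_input_clipped_at_creation(self):
        g = IntensityGrid(np.array([[-1.0, 2.0], [3.0, -4.0]]))
        assert (g.values >= 0).all()
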