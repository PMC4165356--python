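"""Brain demarcation, RMS noise, 2xRMS thresholding, and the four metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from co2asl.activation import ActivationMap
from co2asl.perfusion import session_perfusion
from co2asl.phantom import make_scan_session
from co2asl.quantify import (BrainMask, activated_mask, compute_metrics,
                             demarcate_brain, rms_noise)


class TestDemarcateBrain:
    def test_noiseless_phantom_recovers_brain_ellipse(self, noiseless_spec):
        """On the anatomy-free perfusion baseline the 0.2 fraction-of-max
        threshold demarcates exactly the phantom's brain ellipse."""
        base = session_perfusion(make_scan_session(noiseless_spec, "0", 0))
        mask = demarcate_brain(base)
        np.testing.assert_array_equal(mask.mask, noiseless_spec.brain_mask())
        assert mask.total_slice_area == noiseless_spec.brain_mask().sum()
        assert mask.threshold == pytest.approx(
            0.2 * noiseless_spec.baseline_perfusion)

    def test_all_zero_map_is_no_brain(self):
        with pytest.raises(ValueError, match="no brain"):
            demarcate_brain(np.zeros((8, 8)))

    def test_uniform_positive_map_selects_everything(self):
        mask = demarcate_brain(np.full((8, 8), 5.0))
        assert mask.mask.all()

    def test_absolute_and_otsu_methods(self, noiseless_spec):
        base = session_perfusion(make_scan_session(noiseless_spec, "0", 0))
        brain = noiseless_spec.brain_mask()
        np.testing.assert_array_equal(
            demarcate_brain(base, method="absolute", parameter=50.0).mask, brain)
        np.testing.assert_array_equal(
            demarcate_brain(base, method="otsu").mask, brain)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            demarcate_brain(np.ones((4, 4)), method="banana")


class TestRmsNoise:
    def test_constant_image_is_zero(self):
        mask = BrainMask(mask=np.ones((3, 3), dtype=bool), threshold=0.0)
        assert rms_noise(np.full((3, 3), 4.2), mask) == 0.0

    def test_small_hand_example(self):
        """Masked values {1,1,3,3}: mean 2, population RMS exactly 1."""
        image = np.array([[1.0, 1.0], [3.0, 3.0]])
        mask = BrainMask(mask=np.ones((2, 2), dtype=bool), threshold=0.0)
        assert rms_noise(image, mask) == pytest.approx(1.0, rel=1e-12)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="no pixels"):
            rms_noise(rng.normal(size=(3, 3)), np.zeros((3, 3), dtype=bool))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 100), shift=st.floats(-100, 100))
    def test_scale_and_shift_behaviour(self, scale, shift):
        """Scaling multiplies the RMS by |c|; a constant shift leaves it."""
        rng = np.random.default_rng(9)
        image = rng.normal(size=(6, 6))
        mask = np.ones((6, 6), dtype=bool)
        base = rms_noise(image, mask)
        assert rms_noise(scale * image, mask) == pytest.approx(
            scale * base, rel=1e-9)
        assert rms_noise(image + shift, mask) == pytest.approx(
            base, rel=1e-9, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(values=hnp.arrays(np.float64, (5, 5),
                             elements=st.floats(-1e3, 1e3)))
    def test_matches_two_pass_bruteforce(self, values):
        """Equals an independently coded two-pass variance loop."""
        mask = np.ones((5, 5), dtype=bool)
        flat = [float(v) for v in values.ravel()]
        mean = sum(flat) / len(flat)
        expected = (sum((v - mean) ** 2 for v in flat) / len(flat)) ** 0.5
        assert rms_noise(values, mask) == pytest.approx(expected, rel=1e-10,
                                                        abs=1e-10)


TOY = np.array([[0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 0.9]])


class TestActivatedMask:
    def test_toy_threshold_and_count(self):
        """3x3 toy: mean 0.1, RMS 0.2828..., threshold 0.5657...; exactly the
        0.9 pixel is activated."""
        mask = BrainMask(mask=np.ones((3, 3), dtype=bool), threshold=0.0)
        activated, threshold, rms = activated_mask(TOY, mask)
        assert rms == pytest.approx(np.sqrt(0.08), rel=1e-12)
        assert threshold == pytest.approx(2 * np.sqrt(0.08), rel=1e-12)
        assert activated.sum() == 1 and activated[2, 2]

    def test_zero_map_activates_nothing(self):
        mask = BrainMask(mask=np.ones((3, 3), dtype=bool), threshold=0.0)
        activated, _, _ = activated_mask(np.zeros((3, 3)), mask)
        assert not activated.any()

    def test_invalid_pixels_excluded(self):
        """NaN (invalid-baseline) pixels enter neither the RMS nor the
        activated set."""
        values = np.array([[2.0, 0.0], [0.0, np.nan]])
        act = ActivationMap(values=values, valid=~np.isnan(values))
        mask = BrainMask(mask=np.ones((2, 2), dtype=bool), threshold=0.0)
        activated, threshold, rms = activated_mask(act, mask)
        # RMS over the three valid pixels only: mean 2/3, rms sqrt(8/9)
        assert rms == pytest.approx(np.sqrt(8 / 9), rel=1e-12)
        assert activated[0, 0] and activated.sum() == 1
        assert not activated[1, 1]

    def test_explicit_threshold_bypasses_rms(self):
        mask = BrainMask(mask=np.ones((3, 3), dtype=bool), threshold=0.0)
        activated, threshold, _ = activated_mask(TOY, mask, threshold=0.5)
        assert threshold == 0.5 and activated.sum() == 1


class TestComputeMetrics:
    def _toy_run(self, per_pixel="activated"):
        mask = BrainMask(mask=np.ones((3, 3), dtype=bool), threshold=0.0)
        activated, threshold, rms = activated_mask(TOY, mask)
        return compute_metrics(TOY, activated, mask, threshold=threshold,
                               rms=rms, per_pixel=per_pixel)

    def test_toy_four_metrics(self):
        m = self._toy_run()
        assert m.normalized_activation_intensity == pytest.approx(0.9)
        assert m.activation_area == 1
        assert m.activation_intensity_per_pixel == pytest.approx(0.9)
        assert m.normalized_activation_area == pytest.approx(1 / 9)

    def test_slice_denominator_variant(self):
        m = self._toy_run(per_pixel="slice")
        assert m.activation_intensity_per_pixel == pytest.approx(0.9 / 9)
        assert m.per_pixel_convention == "slice"

    def test_no_activation_all_zero(self):
        mask = BrainMask(mask=np.ones((3, 3), dtype=bool), threshold=0.0)
        m = compute_metrics(np.zeros((3, 3)),
                            np.zeros((3, 3), dtype=bool), mask)
        assert (m.normalized_activation_intensity == 0
                and m.activation_area == 0
                and m.activation_intensity_per_pixel == 0
                and m.normalized_activation_area == 0)

    def test_linearity_under_fixed_threshold(self, rng):
        """Doubling activated values doubles intensity metrics, areas fixed."""
        values = rng.uniform(0, 1, (6, 6))
        mask = BrainMask(mask=np.ones((6, 6), dtype=bool), threshold=0.0)
        activated = values > 0.6
        m1 = compute_metrics(values, activated, mask)
        m2 = compute_metrics(2 * values, activated, mask)
        assert m2.normalized_activation_intensity == pytest.approx(
            2 * m1.normalized_activation_intensity, rel=1e-12)
        assert m2.activation_intensity_per_pixel == pytest.approx(
            2 * m1.activation_intensity_per_pixel, rel=1e-12)
        assert m2.activation_area == m1.activation_area
        assert m2.normalized_activation_area == m1.normalized_activation_area

    def test_internal_consistency_on_phantom_run(self, default_spec):
        """area <= slice area; per-pixel x area = intensity; normalized
        area = area / slice area."""
        from co2asl.activation import change_map, normalize_to_baseline
        from co2asl.perfusion import concentration_perfusion
        base = concentration_perfusion(
            [session_perfusion(make_scan_session(default_spec, "0", i))
             for i in range(4)])
        conc = concentration_perfusion(
            [session_perfusion(make_scan_session(default_spec, "20", i))
             for i in range(4)])
        brain = demarcate_brain(base)
        act = normalize_to_baseline(change_map(conc, base), base, brain.mask)
        activated, threshold, rms = activated_mask(act, brain)
        m = compute_metrics(act, activated, brain, threshold=threshold, rms=rms)
        assert 0 < m.activation_area <= brain.total_slice_area
        assert m.activation_intensity_per_pixel * m.activation_area == \
            pytest.approx(m.normalized_activation_intensity, rel=1e-12)
        assert m.normalized_activation_area == pytest.approx(
            m.activation_area / brain.total_slice_area, rel=1e-12)
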