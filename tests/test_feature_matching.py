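import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbnrr.core_io import Image3D, LabelImage
from pbnrr.feature_matching import (
    BlockSpec,
    block_match,
    ncc,
    select_feature_points,
)

from conftest import textured_image


class TestNcc:
    def test_self_correlation_is_one(self):
        a = np.arange(27, dtype=float).reshape(3, 3, 3)
        assert ncc(a, a) == (1.0, True)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((4, 4, 4))
        val = ncc(a, 2.0 * a + 3.0)
        assert val.defined and val.value == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_orthogonal_patterns(self):
        a = np.array([1.0, -1.0, 1.0, -1.0]).reshape(2, 2, 1)
        b = np.array([1.0, 1.0, -1.0, -1.0]).reshape(2, 2, 1)
        val = ncc(a, b)
        assert val.defined and val.value == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_flagged(self):
        a = np.ones((3, 3, 3))
        b = np.arange(27, dtype=float).reshape(3, 3, 3)
        assert ncc(a, b) == (0.0, False)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ncc(np.zeros((2, 2, 2)), np.zeros((2, 2, 1)))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_bounded_on_random_blocks(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((3, 3, 3))
        b = rng.standard_normal((3, 3, 3))
        val = ncc(a, b)
        assert -1.0 <= val.value <= 1.0


class TestFeatureSelection:
    def test_constant_image_yields_empty_selection(self):
        img = Image3D(data=np.full((20, 20, 20), 7.0))
        pts = select_feature_points(img, BlockSpec(), fraction=1.0)
        assert len(pts) == 0

    def test_textured_cube_attracts_all_selections(self):
        rng = np.random.default_rng(1)
        data = np.zeros((32, 32, 32))
        data[10:21, 10:21, 10:21] = rng.standard_normal((11, 11, 11)) * 50
        img = Image3D(data=data)
        spec = BlockSpec(B=(2, 2, 2))
        pts = select_feature_points(img, spec, fraction=0.005)
        assert len(pts) > 0
        # every center's block must overlap the textured cube
        assert np.all(pts >= 10 - 2) and np.all(pts <= 20 + 2)

    def test_fraction_one_returns_all_positive_variance_centers(self):
        img = textured_image((16, 16, 16), seed=2)
        spec = BlockSpec(B=(2, 2, 2))
        pts = select_feature_points(img, spec, fraction=1.0, min_spacing=0.0)
        inner = np.prod(np.asarray(img.shape) - 4)
        assert len(pts) == inner  # random texture: all variances positive

    def test_min_spacing_thinning(self):
        img = textured_image((24, 24, 24), seed=3)
        pts = select_feature_points(img, BlockSpec(), fraction=1.0,
                                    min_spacing=4.0)
        d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1).astype(float)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 16.0

    def test_no_fitting_block_raises(self):
        img = Image3D(data=np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="fits"):
            select_feature_points(img, BlockSpec(B=(3, 3, 3)), fraction=0.5)


class TestBlockMatch:
    def _translation_pair(self, shift=(3, 0, 0), seed=0, spacing=(1.0, 1.0, 1.0)):
        floating = textured_image((32, 32, 32), seed=seed, spacing=spacing)
        fixed = Image3D(np.roll(floating.data, shift, axis=(0, 1, 2)),
                        spacing=spacing)
        return floating, fixed

    def test_integer_translation_recovered_exactly(self):
        floating, fixed = self._translation_pair((3, 0, 0))
        spec = BlockSpec(B=(3, 3, 3), W=(5, 5, 5))
        pts = select_feature_points(floating, spec, fraction=0.05,
                                    margin=(8, 8, 8), min_spacing=2.0)
        ms = block_match(floating, fixed, pts, spec)
        assert len(ms) > 20
        np.testing.assert_allclose(ms.displacements,
                                   np.tile([3.0, 0, 0], (len(ms), 1)))
        np.testing.assert_allclose(ms.confidences, 1.0, atol=1e-12)

    def test_displacements_scale_with_spacing(self):
        floating, fixed = self._translation_pair((0, 2, 0), seed=4,
                                                 spacing=(1.0, 0.5, 2.0))
        spec = BlockSpec(B=(2, 2, 2), W=(3, 3, 3))
        pts = select_feature_points(floating, spec, fraction=0.02,
                                    margin=(5, 5, 5), min_spacing=2.0)
        ms = block_match(floating, fixed, pts, spec)
        np.testing.assert_allclose(ms.displacements,
                                   np.tile([0.0, 1.0, 0.0], (len(ms), 1)))

    def test_zero_window_forces_zero_displacement(self):
        floating, fixed = self._translation_pair((1, 0, 0))
        spec = BlockSpec(B=(2, 2, 2), W=(0, 0, 0))
        pts = np.array([[16, 16, 16], [10, 12, 14]])
        ms = block_match(floating, fixed, pts, spec, min_confidence=-1.0)
        np.testing.assert_array_equal(ms.displacements, 0.0)

    def test_constant_fixed_window_dropped(self):
        floating = textured_image((24, 24, 24), seed=5)
        fixed = Image3D(data=np.zeros((24, 24, 24)))
        spec = BlockSpec(B=(2, 2, 2), W=(2, 2, 2))
        ms = block_match(floating, fixed, np.array([[12, 12, 12]]), spec)
        assert len(ms) == 0

    def test_affine_intensity_rescaling_invariance(self):
        floating, fixed = self._translation_pair((2, 1, 0), seed=6)
        spec = BlockSpec(B=(2, 2, 2), W=(3, 3, 3))
        pts = select_feature_points(floating, spec, fraction=0.02,
                                    margin=(5, 5, 5), min_spacing=2.0)
        ms1 = block_match(floating, fixed, pts, spec)
        floating2 = Image3D(1.7 * floating.data + 11.0)
        fixed2 = Image3D(0.4 * fixed.data - 3.0)
        ms2 = block_match(floating2, fixed2, pts, spec)
        np.testing.assert_array_equal(ms1.points, ms2.points)
        np.testing.assert_array_equal(ms1.displacements, ms2.displacements)
        np.testing.assert_allclose(ms1.confidences, ms2.confidences, atol=1e-9)

    def test_ncc_evaluation_count_matches_search_volume(self):
        floating, fixed = self._translation_pair((1, 1, 1), seed=7)
        spec = BlockSpec(B=(2, 2, 2), W=(2, 3, 1))
        pts = np.array([[12, 12, 12], [15, 10, 16], [9, 14, 11]])
        ms = block_match(floating, fixed, pts, spec, min_confidence=-1.0)
        per_point = np.prod([2 * w + 1 for w in spec.W])
        assert ms.provenance["ncc_evaluations_per_point"] == per_point
        assert ms.provenance["ncc_evaluations"] == per_point * len(pts)

    def test_geometry_mismatch_rejected(self):
        a = textured_image((16, 16, 16))
        b = Image3D(a.data, spacing=(2.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="geometry"):
            block_match(a, b, np.array([[8, 8, 8]]), BlockSpec(B=(2, 2, 2)))

    def test_csv_round_trip(self, tmp_path):
        floating, fixed = self._translation_pair((1, 0, 2), seed=8)
        spec = BlockSpec(B=(2, 2, 2), W=(3, 3, 3))
        pts = select_feature_points(floating, spec, fraction=0.01,
                                    margin=(5, 5, 5), min_spacing=3.0)
        ms = block_match(floating, fixed, pts, spec)
        from pbnrr.feature_matching import MatchSet
        path = tmp_path / "m.csv"
        ms.to_csv(path)
        back = MatchSet.from_csv(path)
        np.testing.assert_array_equal(back.points, ms.points)
        np.testing.assert_allclose(back.displacements, ms.displacements)
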