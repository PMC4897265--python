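"""Radial contour descriptor: geometry, invariances, degenerate inputs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_feature, random_polygon
from keyposes import (
    DegenerateContourError,
    EmptyMaskError,
    RadialFeatureConfig,
    bin_assignment,
    centroid,
    centroid_distances,
    extract_contour,
    pose_feature,
    pose_feature_from_contour,
    summarize_bin,
)


class TestContourExtraction:
    def test_block_boundary_pixels_in_order(self):
        """A centred 3x3 block yields its 8 boundary pixels, each a
        foreground pixel with a 4-neighbour background, in traversal order."""
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        contour = extract_contour(mask)
        assert len(contour) == 8
        # oracle: foreground pixels having a background 4-neighbour
        expected = set()
        for r in range(5):
            for c in range(5):
                if mask[r, c] and any(
                    not (0 <= r + dr < 5 and 0 <= c + dc < 5 and mask[r + dr, c + dc])
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                ):
                    expected.add((c, r))
        assert {tuple(p) for p in contour.astype(int)} == expected
        # ordered traversal: consecutive points are 8-adjacent
        diffs = np.abs(np.diff(np.vstack([contour, contour[:1]]), axis=0))
        assert diffs.max() <= 1

    def test_single_pixel_mask(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        contour = extract_contour(mask)
        assert contour.shape == (1, 2)
        assert tuple(contour[0]) == (1, 1)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            extract_contour(np.zeros((4, 4), bool))

    def test_largest_component_wins(self):
        mask = np.zeros((10, 10), bool)
        mask[1:6, 1:6] = True  # 25 px
        mask[8, 8] = True  # speck
        contour = extract_contour(mask)
        assert (contour[:, 0] <= 5).all() and (contour[:, 1] <= 5).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_every_contour_point_touches_background(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((16, 16), bool)
        r0, c0 = rng.integers(2, 8, size=2)
        mask[r0:r0 + rng.integers(3, 7), c0:c0 + rng.integers(3, 7)] = True
        for x, y in extract_contour(mask).astype(int):
            assert mask[y, x]
            neigh = mask[max(y - 1, 0):y + 2, max(x - 1, 0):x + 2]
            assert neigh.size < 9 or not neigh.all()


class TestGeometrySteps:
    def test_centroid_examples(self):
        assert centroid(np.array([(0, 0), (4, 0), (4, 4), (0, 4)])) == (2, 2)
        assert centroid(np.array([(1, 1)])) == (1, 1)
        assert centroid(np.array([(0, 0), (3, 0), (0, 3)])) == (1, 1)
        with pytest.raises(ValueError):
            centroid(np.empty((0, 2)))

    def test_centroid_distances(self):
        square = np.array([(0, 0), (4, 0), (4, 4), (0, 4)], float)
        np.testing.assert_allclose(
            centroid_distances(square, (2, 2)), np.sqrt(8), rtol=0, atol=1e-12
        )
        assert centroid_distances(np.array([(2.0, 2.0)]), (2, 2))[0] == 0
        assert centroid_distances(np.array([(5.0, 2.0)]), (2, 2))[0] == 3

    def test_bin_assignment_cardinal_directions(self):
        # offsets (0,-2),(2,0),(0,2),(-2,0) about centroid, image y down
        pts = np.array([(0, -2), (2, 0), (0, 2), (-2, 0)], float)
        bins = bin_assignment(pts, (0.0, 0.0), S=4)
        np.testing.assert_array_equal(bins, [2, 1, 4, 3])

    def test_bin_assignment_single_bin_and_centroid_point(self):
        pts = np.array([(1, 1), (-3, 2), (0, 0)], float)
        np.testing.assert_array_equal(bin_assignment(pts, (0.0, 0.0), 1), [1, 1, 1])
        # a point exactly at the centroid goes to bin 1 regardless of S
        assert bin_assignment(np.array([(0.0, 0.0)]), (0.0, 0.0), 8)[0] == 1

    def test_bin_assignment_rejects_bad_S(self):
        with pytest.raises(ValueError):
            bin_assignment(np.array([(1.0, 0.0)]), (0.0, 0.0), 0)

    @pytest.mark.parametrize(
        "fn,dists,expected",
        [
            ("max", [1, 3, 2], 3.0),
            ("range", [1, 3, 2], 2.0),
            ("variance", [1, 3], 2.0),  # sum of squared deviations, no division
            ("max", [], 0.0),
            ("range", [], 0.0),
            ("variance", [], 0.0),
        ],
    )
    def test_summarize_bin(self, fn, dists, expected):
        assert summarize_bin(dists, fn) == expected


class TestPoseFeature:
    def test_square_mask_symmetry(self):
        mask = np.zeros((21, 21), bool)
        mask[5:16, 5:16] = True
        f = pose_feature(mask, RadialFeatureConfig(S=4, summary="max"))
        np.testing.assert_allclose(f.values, 0.25, rtol=0, atol=1e-12)
        assert not f.degenerate

    def test_translation_invariance_exact(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((40, 40), bool)
        mask[8:20, 10:25] = True
        mask[12:30, 14:18] = True
        cfg = RadialFeatureConfig(S=12, summary="range")
        base = pose_feature(mask, cfg).values
        for dy, dx in [(3, 5), (-2, 4), (6, -7)]:
            shifted = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
            np.testing.assert_array_equal(pose_feature(shifted, cfg).values, base)

    def test_circle_contour_is_degenerate_under_range(self):
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        circle = np.stack([10 * np.cos(theta), 10 * np.sin(theta)], axis=1)
        f = pose_feature_from_contour(circle, RadialFeatureConfig(S=12, summary="range"))
        assert f.degenerate
        np.testing.assert_array_equal(f.values, 0.0)

    def test_short_contour_rejected(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(DegenerateContourError):
            pose_feature(mask, RadialFeatureConfig(S=4, summary="max"))

    @given(st.integers(0, 2**31 - 1), st.sampled_from(["variance", "max", "range"]),
           st.integers(1, 24))
    @settings(max_examples=60, deadline=None)
    def test_unit_sum_length_nonnegative(self, seed, summary, S):
        pts = random_polygon(np.random.default_rng(seed))
        f = pose_feature_from_contour(pts, RadialFeatureConfig(S=S, summary=summary))
        assert len(f.values) == S
        assert (f.values >= 0).all()
        if not f.degenerate:
            assert abs(f.values.sum() - 1.0) < 1e-9

    @pytest.mark.parametrize("summary", ["max", "range"])
    def test_scale_invariance_on_contour(self, summary):
        rng = np.random.default_rng(3)
        pts = random_polygon(rng, n=80)
        cfg = RadialFeatureConfig(S=10, summary=summary)
        c = pts.mean(axis=0)
        for k in (0.5, 2.0, 7.3):
            scaled = c + k * (pts - c)
            np.testing.assert_allclose(
                pose_feature_from_contour(scaled, cfg).values,
                pose_feature_from_contour(pts, cfg).values,
                rtol=0, atol=1e-9,
            )

    def test_scale_invariance_on_rasterized_masks(self):
        """Doubling the raster resolution changes the feature by at most
        0.05 in L1 (quantisation is the only source of discrepancy)."""
        mask = np.zeros((32, 32), bool)
        mask[6:26, 9:23] = True
        mask[10:16, 4:28] = True
        cfg = RadialFeatureConfig(S=12, summary="max")
        doubled = np.kron(mask, np.ones((2, 2), bool))
        f1 = pose_feature(mask, cfg).values
        f2 = pose_feature(doubled, cfg).values
        assert np.abs(f1 - f2).sum() <= 0.05

    def test_rotation_by_bin_angle_cycles_feature(self):
        rng = np.random.default_rng(11)
        S = 12
        cfg = RadialFeatureConfig(S=S, summary="range")
        pts = random_polygon(rng, n=120)
        c = pts.mean(axis=0)
        base = pose_feature_from_contour(pts, cfg).values
        for k in (1, 3, 7):
            delta = np.radians(k * 360.0 / S)
            dx, dy = (pts - c).T
            rotated = np.stack(
                [dx * np.cos(delta) + dy * np.sin(delta),
                 dy * np.cos(delta) - dx * np.sin(delta)], axis=1
            ) + c
            np.testing.assert_allclose(
                pose_feature_from_contour(rotated, cfg).values,
                np.roll(base, k), rtol=0, atol=1e-9,
            )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            pts = random_polygon(rng)
            S = int(rng.integers(1, 30))
            summary = ("variance", "max", "range")[int(rng.integers(3))]
            got = pose_feature_from_contour(
                pts, RadialFeatureConfig(S=S, summary=summary)
            ).values
            want = brute_force_feature(pts, S, summary)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-9)
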