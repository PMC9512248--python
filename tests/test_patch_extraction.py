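"""Patch vetting (connectivity + 35% rule) and canonical alignment."""

import numpy as np
import pytest

from shadowedge.containers import ImagePatch
from shadowedge.patch_extraction import (
    LabeledEdgeImage,
    accept_patch,
    align_patch,
    extract_patches,
    sample_edge_centers,
    to_grayscale,
)
from shadowedge.patch_extraction import _edge_axis_angle
from shadowedge.synthetic_data import make_pseudo_scene


class TestToGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((1, 1, 1), 0.9999), ((0, 0, 0), 0.0), ((1, 0, 0), 0.2989)],
    )
    def test_standard_coefficients(self, rgb, expected):
        assert to_grayscale(np.array(rgb, dtype=float)) == pytest.approx(
            expected
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.array([-0.1, 0.5, 0.5]))


class TestSampleEdgeCenters:
    def _labeled(self, maps):
        img = np.zeros(maps[0].shape)
        return LabeledEdgeImage(image=img, edge_maps=maps)

    def test_single_annotator_without_replacement(self):
        m = np.zeros((50, 50), bool)
        pix = [(3, 4), (10, 10), (20, 30), (40, 5), (7, 49)]
        for r, c in pix:
            m[r, c] = True
        centers = sample_edge_centers(self._labeled([m]), 5, seed=0)
        assert sorted(centers) == sorted(pix)

    def test_annotators_cycle_in_order(self):
        maps = []
        for a in range(4):
            m = np.zeros((50, 50), bool)
            m[a, :] = True  # annotator a labels row a
            maps.append(m)
        centers = sample_edge_centers(self._labeled(maps), 8, seed=1)
        rows = [r for r, _ in centers]
        assert rows == [0, 1, 2, 3, 0, 1, 2, 3]

    def test_fixed_seed_reproducible(self):
        m = np.zeros((50, 50), bool)
        m[10:40, 25] = True
        a = sample_edge_centers(self._labeled([m]), 10, seed=3)
        b = sample_edge_centers(self._labeled([m]), 10, seed=3)
        assert a == b

    def test_empty_maps_warn_and_return_empty(self):
        with pytest.warns(UserWarning):
            out = sample_edge_centers(
                self._labeled([np.zeros((50, 50), bool)]), 5, seed=0
            )
        assert out == []


class TestAcceptPatch:
    def test_straight_vertical_line_accepted_half_split(self):
        m = np.zeros((40, 40), bool)
        m[:, 20] = True
        ok, (r1, r2) = accept_patch(m)
        assert ok
        assert {r1.sum(), r2.sum()} == {800, 760}

    def test_corner_clipping_diagonal_rejected_by_35_rule(self):
        m = np.zeros((40, 40), bool)
        for i in range(25):
            m[i, 24 - i] = True  # cuts off ~19% corner triangle
        ok, _ = accept_patch(m)
        assert not ok

    def test_crossing_lines_rejected(self):
        m = np.zeros((40, 40), bool)
        m[:, 20] = True
        m[20, :] = True
        assert not accept_patch(m)[0]

    def test_two_disconnected_segments_rejected(self):
        m = np.zeros((40, 40), bool)
        m[:, 10] = True
        m[:, 30] = True
        assert not accept_patch(m)[0]

    def test_empty_map_rejected(self):
        assert not accept_patch(np.zeros((40, 40), bool))[0]

    def test_diagonal_path_does_not_leak(self):
        """An 8-connected diagonal line separates the regions under the
        4-connectivity background convention."""
        m = np.eye(40, dtype=bool)
        ok, masks = accept_patch(m)
        assert ok

    def test_mirror_gives_same_decision(self, rng):
        for _ in range(20):
            m = np.zeros((40, 40), bool)
            col = int(rng.integers(5, 35))
            slope = rng.integers(-1, 2)
            for r in range(40):
                c = int(np.clip(col + slope * r // 4, 0, 39))
                m[r, c] = True
            assert accept_patch(m)[0] == accept_patch(m[:, ::-1])[0]

    def test_masks_partition_patch(self):
        m = np.zeros((40, 40), bool)
        m[:, 16] = True
        ok, (r1, r2) = accept_patch(m)
        combined = r1.astype(int) + r2.astype(int) + m.astype(int)
        assert np.all(combined == 1)


class TestAlignPatch:
    def _patch(self, pixels, edge_mask):
        ok, masks = accept_patch(edge_mask)
        assert ok
        return ImagePatch(
            pixels=pixels, region_masks=masks, edge_mask=edge_mask
        )

    def test_vertical_dark_left_unchanged(self, vertical_step_patch):
        out = align_patch(vertical_step_patch)
        np.testing.assert_allclose(out.pixels, vertical_step_patch.pixels)

    def test_horizontal_edge_rotated_to_vertical(self):
        pixels = np.full((40, 40), 0.2)
        pixels[20:, :] = 0.8
        edge = np.zeros((40, 40), bool)
        edge[20, :] = True
        out = align_patch(self._patch(pixels, edge))
        assert abs(_edge_axis_angle(out.edge_mask)) < np.deg2rad(3)
        assert out.pixels[:, :20].mean() <= out.pixels[:, 20:].mean()

    def test_left_brighter_gets_mirrored(self):
        pixels = np.full((40, 40), 0.8)
        pixels[:, 20:] = 0.2
        edge = np.zeros((40, 40), bool)
        edge[:, 20] = True
        out = align_patch(self._patch(pixels, edge))
        np.testing.assert_allclose(out.pixels, pixels[:, ::-1])

    def test_mirror_preserves_pixel_multiset(self):
        pixels = np.linspace(1, 0, 1600).reshape(40, 40)
        edge = np.zeros((40, 40), bool)
        edge[:, 20] = True
        out = align_patch(self._patch(pixels, edge))
        np.testing.assert_allclose(
            np.sort(out.pixels.ravel()), np.sort(pixels.ravel())
        )

    def test_rotated_masks_still_partition(self):
        pixels = np.full((40, 40), 0.2)
        pixels[20:, :] = 0.8
        edge = np.zeros((40, 40), bool)
        edge[20, :] = True
        out = align_patch(self._patch(pixels, edge))
        total = (
            out.region_masks[0].astype(int)
            + out.region_masks[1].astype(int)
            + out.edge_mask.astype(int)
        )
        assert np.all(total == 1)

    def test_single_pixel_edge_rejected(self):
        pixels = np.random.default_rng(0).random((40, 40))
        edge = np.zeros((40, 40), bool)
        edge[20, 20] = True
        patch = ImagePatch(
            pixels=pixels,
            region_masks=(edge.copy(), ~edge),
            edge_mask=edge,
        )
        with pytest.raises(ValueError):
            align_patch(patch)


class TestExtractPatches:
    def test_pseudo_scene_roundtrip(self):
        img, maps = make_pseudo_scene(11, 128, n_edges=3)
        lab = LabeledEdgeImage(
            image=img, edge_maps=maps, category="occlusion", name="s11"
        )
        patches = extract_patches(lab, 60, seed=2)
        assert len(patches) > 0
        for q in patches:
            assert q.aligned
            assert q.pixels.shape == (40, 40)
            # darker side left after alignment
            assert q.pixels[:, :20].mean() <= q.pixels[:, 20:].mean() + 1e-9

    def test_no_edges_yields_no_patches(self):
        img, maps = make_pseudo_scene(0, 128, n_edges=0)
        lab = LabeledEdgeImage(image=img, edge_maps=maps)
        with pytest.warns(UserWarning):
            assert extract_patches(lab, 10, seed=0) == []
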