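"""Synthetic shadow/occlusion generator: determinism, contrast control,
category structure, observer simulation."""

import numpy as np
import pytest

from shadowedge.patch_statistics import (
    high_freq_proportion,
    michelson_contrast,
    rms_contrast,
)
from shadowedge.synthetic_data import (
    DatasetConfig,
    SynthPatchParams,
    TextureSpectrum,
    make_dataset,
    make_patch,
    make_pseudo_scene,
    make_step_edge,
    make_texture,
    simulate_observers,
)


class TestMakeTexture:
    def test_deterministic_for_fixed_seed(self):
        a = make_texture(7, 40)
        b = make_texture(7, 40)
        np.testing.assert_array_equal(a, b)

    def test_lowpass_weighting_reduces_high_frequency_power(self):
        lowpass = make_texture(3, 40, TextureSpectrum(falloff=3.0))
        white = make_texture(3, 40, TextureSpectrum(falloff=0.0))
        assert high_freq_proportion(lowpass) < high_freq_proportion(white)

    def test_different_seeds_nearly_uncorrelated(self):
        cors = []
        for s in range(20):
            a = make_texture(2 * s, 40).ravel()
            b = make_texture(2 * s + 1, 40).ravel()
            cors.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_texture(0, 4)


class TestMakeStepEdge:
    def test_sharp_step_contrast_exact(self):
        p = make_step_edge(0.4, 0.0, 40)
        assert michelson_contrast(p) == pytest.approx(0.4, abs=1e-6)
        assert rms_contrast(p) > 0

    def test_blur_reduces_high_frequency_content(self):
        sharp = make_step_edge(0.2, 0.0, 40)
        blurred = make_step_edge(0.2, 4.0, 40)
        assert high_freq_proportion(blurred.pixels) < high_freq_proportion(
            sharp.pixels
        )

    def test_blurred_contrast_still_exact(self):
        p = make_step_edge(0.6, 3.0, 40)
        assert michelson_contrast(p) == pytest.approx(0.6, abs=1e-6)

    def test_zero_contrast_is_uniform(self):
        p = make_step_edge(0.0, 0.0, 40)
        assert rms_contrast(p) == 0.0

    def test_contrast_one_rejected(self):
        with pytest.raises(ValueError):
            make_step_edge(1.0, 0.0, 40)

    def test_mean_intensity_inside_unit_interval(self):
        for c, b in [(0.2, 0.0), (0.6, 2.0), (0.9, 5.0)]:
            p = make_step_edge(c, b, 40)
            assert 0 < p.pixels.mean() < 1


class TestMakePatch:
    def _shadow(self, **kw):
        base = dict(
            category="shadow",
            contrast_target=0.5,
            blur_sigma=3.0,
            texture_seed_left=11,
            texture_seed_right=11,
            texture_similarity=1.0,
        )
        base.update(kw)
        return SynthPatchParams(**base)

    def _occlusion(self, **kw):
        base = dict(
            category="occlusion",
            contrast_target=0.0,
            blur_sigma=0.0,
            texture_seed_left=11,
            texture_seed_right=12,
            texture_similarity=0.0,
        )
        base.update(kw)
        return SynthPatchParams(**base)

    def test_shadow_regions_differ_with_common_texture(self):
        p = make_patch(self._shadow())
        m1, m2 = p.region_masks
        assert p.pixels[m1].mean() < p.pixels[m2].mean()
        assert michelson_contrast(p) == pytest.approx(0.5, abs=1e-6)

    def test_zero_contrast_occlusion_has_equal_means_different_textures(self):
        p = make_patch(self._occlusion())
        m1, m2 = p.region_masks
        assert p.pixels[m1].mean() == pytest.approx(p.pixels[m2].mean())
        assert michelson_contrast(p) == pytest.approx(0.0, abs=1e-6)
        # textures genuinely differ across the boundary
        left_cols = p.pixels[:, :19]
        right_cols = p.pixels[:, 20:39]
        r = np.corrcoef(left_cols.ravel(), right_cols.ravel())[0, 1]
        assert abs(r) < 0.3

    def test_invalid_parameter_combinations_rejected(self):
        with pytest.raises(ValueError):
            self._shadow(texture_similarity=0.5)
        with pytest.raises(ValueError):
            self._shadow(contrast_target=0.0)
        with pytest.raises(ValueError):
            self._occlusion(blur_sigma=1.0)
        with pytest.raises(ValueError):
            self._occlusion(contrast_target=1.0)

    def test_partition_covers_patch(self):
        p = make_patch(self._shadow())
        m1, m2 = p.region_masks
        combined = m1.astype(int) + m2.astype(int) + p.edge_mask.astype(int)
        assert np.all(combined == 1)


class TestMakeDataset:
    def test_bit_exact_reproducibility(self):
        a, ma = make_dataset(10, seed=5)
        b, mb = make_dataset(10, seed=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.pixels, pb.pixels)
        assert ma.equals(mb)

    def test_contrast_control_within_tolerance(self):
        patches, manifest = make_dataset(50, seed=2)
        for patch, target in zip(patches, manifest["contrast_target"]):
            assert michelson_contrast(patch) == pytest.approx(
                target, abs=1e-6
            )

    def test_category_signal_in_high_frequencies(self):
        """Median pi_h is higher for occlusions than shadows (penumbral
        blur removes high spatial frequencies from shadow boundaries)."""
        patches, manifest = make_dataset(150, seed=3)
        pih = np.array([high_freq_proportion(q.pixels) for q in patches])
        occ = manifest["category"].to_numpy() == "occlusion"
        assert np.median(pih[occ]) > np.median(pih[~occ])

    def test_pseudo_image_grouping(self):
        cfg = DatasetConfig(patches_per_image=25)
        _, manifest = make_dataset(100, seed=1, config=cfg)
        sizes = manifest.groupby("pseudo_image_id").size()
        assert (sizes == 25).all()
        mixed = manifest.groupby("pseudo_image_id")["category"].nunique()
        assert (mixed == 1).all()


class TestMakePseudoScene:
    def test_no_edges_yields_empty_maps(self):
        _, maps = make_pseudo_scene(0, 128, n_edges=0)
        assert all(m.sum() == 0 for m in maps)

    def test_maps_are_binary_and_match_image(self):
        img, maps = make_pseudo_scene(1, 120, n_edges=3)
        assert img.shape == (120, 120)
        for m in maps:
            assert m.dtype == bool and m.shape == img.shape

    def test_small_scene_rejected(self):
        with pytest.raises(ValueError):
            make_pseudo_scene(0, 64)


class TestSimulateObservers:
    def test_all_ones_probabilities(self):
        obs = simulate_observers([1.0, 1.0, 1.0], 20, seed=0)
        assert obs.responses.mean() == 1.0

    def test_proportions_converge_to_probs(self):
        probs = np.full(30, 0.5)
        obs = simulate_observers(probs, 10000, seed=1)
        empirical = obs.responses.mean(axis=0)
        assert np.max(np.abs(empirical - 0.5)) < 0.02

    def test_fixed_seed_reproducible(self):
        a = simulate_observers([0.2, 0.8], 50, seed=9)
        b = simulate_observers([0.2, 0.8], 50, seed=9)
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_observers([1.5], 5, seed=0)
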