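"""Synthetic shadow / occlusion patch generator and simulated observers.

The generator emulates the statistical structure that separates the two
edge classes in natural scenes:

* **Occlusions**: two distinct textures abutting a sharp, straight
  boundary.  Because the two surfaces are unrelated, their mean luminances
  may be identical (Michelson contrast 0) or very different, so occlusion
  contrasts span both tails of the contrast distribution.
* **Shadows**: a single continuous texture under a multiplicative
  illumination step with penumbral blur.  A shadow requires a luminance
  change, so its contrast is bounded away from zero, and the penumbra
  removes high spatial frequencies at the boundary.

All patches are 40x40, vertically oriented with the darker side on the
left (pre-aligned), with the edge path on the column just left of center,
and with Michelson contrast controlled exactly (an affine intensity map
pins the two region means, so the measured contrast matches the target to
floating-point precision).

Textures are orientation/frequency-weighted Gaussian noise fields squashed
into (0, 1); texture similarity between the two sides of an occlusion is
spanned continuously by interpolating between the spectra of two seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line

from .containers import ImagePatch

__all__ = [
    "SynthPatchParams",
    "TextureSpectrum",
    "DatasetConfig",
    "SimulatedObserverSet",
    "make_texture",
    "make_step_edge",
    "make_patch",
    "make_dataset",
    "make_pseudo_scene",
    "simulate_observers",
]

PATCH_SIZE = 40


@dataclass(frozen=True)
class TextureSpectrum:
    """Orientation/frequency weighting of a noise texture.

    ``falloff`` is the exponent of the 1/f^falloff radial amplitude
    envelope (natural textures are ~1); ``orientation`` and ``anisotropy``
    add an optional oriented energy bias (anisotropy 0 = isotropic).
    """

    falloff: float = 1.2
    orientation: float = 0.0
    anisotropy: float = 0.0


@dataclass(frozen=True)
class SynthPatchParams:
    """Parameters of one synthetic patch.

    Invariants: shadows have ``texture_similarity == 1`` and
    ``contrast_target > 0``; occlusions have ``blur_sigma == 0`` at the
    boundary.
    """

    category: str  # "shadow" | "occlusion"
    contrast_target: float
    blur_sigma: float
    texture_seed_left: int
    texture_seed_right: int
    texture_similarity: float = 1.0
    patch_size: int = PATCH_SIZE
    spectrum: TextureSpectrum = TextureSpectrum()

    def __post_init__(self) -> None:
        if self.category not in ("shadow", "occlusion"):
            raise ValueError(f"unknown category {self.category!r}")
        if not 0.0 <= self.contrast_target < 1.0:
            raise ValueError("contrast_target must be in [0, 1)")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if not 0.0 <= self.texture_similarity <= 1.0:
            raise ValueError("texture_similarity must be in [0, 1]")
        if self.category == "shadow":
            if self.texture_similarity != 1.0:
                raise ValueError("shadow patches have texture_similarity = 1")
            if self.contrast_target <= 0:
                raise ValueError("shadow patches require contrast_target > 0")
        if self.category == "occlusion" and self.blur_sigma != 0:
            raise ValueError("occlusion boundaries are sharp (blur_sigma = 0)")


@dataclass
class SimulatedObserverSet:
    """Bernoulli observers standing in for a human response table."""

    n_observers: int
    response_probs: np.ndarray
    responses: np.ndarray  # observers x images, values in {0, 1}
    seed: int


def _noise_field(seed: int, size: int, spectrum: TextureSpectrum) -> np.ndarray:
    """Zero-mean, unit-variance spectrally weighted Gaussian noise."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    F = np.fft.fft2(white)
    f1 = np.fft.fftfreq(size) * size  # cycles/image
    fx, fy = np.meshgrid(f1, f1)
    f = np.sqrt(fx**2 + fy**2)
    envelope = np.zeros_like(f)
    nz = f > 0
    envelope[nz] = f[nz] ** (-spectrum.falloff)
    if spectrum.anisotropy > 0:
        phi = np.arctan2(fy, fx)
        envelope *= np.exp(
            spectrum.anisotropy * np.cos(2.0 * (phi - spectrum.orientation))
        )
    field = np.real(np.fft.ifft2(F * envelope))
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def make_texture(
    seed: int,
    size: int = PATCH_SIZE,
    spectral_params: TextureSpectrum = TextureSpectrum(),
) -> np.ndarray:
    """Reproducible zero-mean texture field with the requested spectrum."""
    if size < 8:
        raise ValueError("texture size must be >= 8")
    return _noise_field(seed, size, spectral_params)


def _unit_texture(field: np.ndarray) -> np.ndarray:
    """Squash a unit-variance field smoothly into (0, 1)."""
    return 0.5 + 0.5 * np.tanh(field / 2.0)


def _mixed_field(
    seed_a: int, seed_b: int, similarity: float, size: int,
    spectrum: TextureSpectrum,
) -> np.ndarray:
    """Field correlated ``similarity`` with the seed_a field."""
    fa = _noise_field(seed_a, size, spectrum)
    if similarity >= 1.0:
        return fa
    fb = _noise_field(seed_b, size, spectrum)
    return similarity * fa + np.sqrt(1.0 - similarity**2) * fb


def _circular_gaussian_blur_1d(profile: np.ndarray, sigma: float) -> np.ndarray:
    """Exact circular Gaussian blur via the frequency domain.

    Multiplies the profile's DFT by exp(-2 pi^2 sigma^2 f^2) (the Fourier
    transform of a Gaussian), the circular-convolution definition of
    penumbral blur used throughout the generator.  Unlike a truncated
    spatial kernel this makes spectral attenuation exact, so statistics
    like pi_h are strictly decreasing in sigma.
    """
    if sigma <= 0:
        return profile.astype(float)
    n = profile.size
    f = np.fft.fftfreq(n)  # cycles/pixel
    envelope = np.exp(-2.0 * np.pi**2 * sigma**2 * f**2)
    return np.real(np.fft.ifft(np.fft.fft(profile) * envelope))


def _partition_masks(size: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left region, right region, and the 1-pixel edge-path column."""
    edge_col = size // 2 - 1
    cols = np.arange(size)
    left = np.zeros((size, size), dtype=bool)
    right = np.zeros((size, size), dtype=bool)
    edge = np.zeros((size, size), dtype=bool)
    left[:, cols < edge_col] = True
    right[:, cols > edge_col] = True
    edge[:, edge_col] = True
    return left, right, edge


def _pin_region_means(
    pixels: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    contrast: float,
    mean_level: float = 0.5,
) -> np.ndarray:
    """Affine map making the region means exactly mean_level*(1 -+ c).

    A global affine transform leaves spatial structure intact while
    pinning both region means, so the measured Michelson contrast equals
    the target exactly (up to float rounding).
    """
    mu1 = pixels[left].mean()
    mu2 = pixels[right].mean()
    t1 = mean_level * (1.0 - contrast)
    t2 = mean_level * (1.0 + contrast)
    if np.isclose(mu1, mu2):
        if contrast > 0:
            raise ValueError("cannot impose nonzero contrast on equal means")
        return pixels - mu1 + mean_level
    a = (t2 - t1) / (mu2 - mu1)
    b = t1 - a * mu1
    return a * pixels + b


def make_step_edge(
    contrast_target: float,
    blur_sigma: float,
    size: int = PATCH_SIZE,
) -> ImagePatch:
    """Vertical luminance step (dark left), Gaussian-blurred, contrast-exact.

    The step is blurred with a Gaussian of ``blur_sigma`` pixels and then
    affinely rescaled so the Michelson contrast measured from the two
    half-patch means equals ``contrast_target`` to within 1e-6.
    """
    if not 0.0 <= contrast_target < 1.0:
        raise ValueError(
            "contrast_target must be in [0, 1): the Michelson contrast of "
            "positive intensities is < 1"
        )
    cols = np.arange(size)
    profile = np.where(cols < size // 2, 0.3, 0.7).astype(float)
    profile = _circular_gaussian_blur_1d(profile, blur_sigma)
    pixels = np.tile(profile, (size, 1))
    left = np.tile(cols < size // 2, (size, 1))
    right = ~left
    if contrast_target == 0:
        pixels = np.full((size, size), 0.5)
    else:
        pixels = _pin_region_means(pixels, left, right, contrast_target)
    return ImagePatch(
        pixels=pixels,
        region_masks=(left, right),
        edge_mask=None,
        aligned=True,
        meta={"blur_sigma": blur_sigma, "contrast_target": contrast_target},
    )


def make_patch(params: SynthPatchParams) -> ImagePatch:
    """Build one labeled synthetic patch with its partition masks.

    Shadows are a single texture multiplied by a blurred illumination step
    (texture continuity is preserved across the boundary); occlusions join
    two textures at a sharp boundary, each side shifted/scaled to its
    target mean.  In both cases the final affine step pins the two region
    means so measured Michelson contrast equals ``contrast_target``.
    """
    size = params.patch_size
    left, right, edge = _partition_masks(size)
    c = params.contrast_target

    if params.category == "shadow":
        field = _noise_field(params.texture_seed_left, size, params.spectrum)
        texture = 0.5 + 0.15 * np.tanh(field / 2.0)  # ~30% relative depth
        cols = np.arange(size)
        # multiplicative illumination with the attenuation that yields the
        # target Michelson contrast, so the final affine step is ~identity
        attenuation = (1.0 - c) / (1.0 + c)
        illum = np.where(cols < size // 2 - 1, attenuation, 1.0).astype(float)
        illum = _circular_gaussian_blur_1d(illum, params.blur_sigma)
        pixels = texture * np.tile(illum, (size, 1))
        pixels = _pin_region_means(pixels, left, right, c)
    else:
        f_left = _noise_field(params.texture_seed_left, size, params.spectrum)
        f_right = _mixed_field(
            params.texture_seed_left,
            params.texture_seed_right,
            params.texture_similarity,
            size,
            params.spectrum,
        )
        t_left = _unit_texture(f_left)
        t_right = _unit_texture(f_right)
        m1 = 0.5 * (1.0 - c)
        m2 = 0.5 * (1.0 + c)
        # texture amplitude limited so pixels stay within (0, 1) even at
        # high luminance contrast; the same amplitude on both sides keeps
        # the texture cue symmetric
        amp = 0.8 * min(m1, 1.0 - m2, 0.35) if c > 0 else 0.3
        pixels = np.empty((size, size))
        side_l = left | (edge & (np.arange(size)[None, :] == size // 2 - 1))
        pixels[side_l] = m1 + amp * (t_left[side_l] - t_left[left].mean())
        pixels[right] = m2 + amp * (t_right[right] - t_right[right].mean())

    patch = ImagePatch(
        pixels=pixels,
        region_masks=(left, right),
        edge_mask=edge,
        aligned=True,
        category=params.category,
        meta=dataclasses.asdict(params),
    )
    return patch


@dataclass(frozen=True)
class DatasetConfig:
    """Default parameter distributions of the synthetic study conditions.

    Occlusion contrast is a mixture concentrated at low values but
    spanning [0, 0.9] (both contrast tails belong to occlusions); shadow
    contrast is uniform on [0.2, 0.9] (bounded away from 0); shadow
    penumbral blur is uniform on [1, 5] pixels; occlusion texture
    similarity is uniform on [0, 0.5].  Patches are grouped into
    category-pure pseudo-images so the by-image evaluation protocol is
    exercised.
    """

    occlusion_low_contrast_weight: float = 0.5
    occlusion_low_contrast_max: float = 0.25
    occlusion_contrast_max: float = 0.9
    occlusion_similarity_range: Tuple[float, float] = (0.0, 0.5)
    shadow_contrast_range: Tuple[float, float] = (0.2, 0.9)
    shadow_blur_range: Tuple[float, float] = (1.0, 5.0)
    falloff_range: Tuple[float, float] = (0.8, 1.6)
    anisotropy_range: Tuple[float, float] = (0.0, 0.8)
    patches_per_image: int = 50


def _sample_params(
    category: str, rng: np.random.Generator, cfg: DatasetConfig
) -> SynthPatchParams:
    spectrum = TextureSpectrum(
        falloff=rng.uniform(*cfg.falloff_range),
        orientation=rng.uniform(0.0, np.pi),
        anisotropy=rng.uniform(*cfg.anisotropy_range),
    )
    seed_l = int(rng.integers(0, 2**31 - 1))
    seed_r = int(rng.integers(0, 2**31 - 1))
    if category == "shadow":
        return SynthPatchParams(
            category="shadow",
            contrast_target=rng.uniform(*cfg.shadow_contrast_range),
            blur_sigma=rng.uniform(*cfg.shadow_blur_range),
            texture_seed_left=seed_l,
            texture_seed_right=seed_l,
            texture_similarity=1.0,
            spectrum=spectrum,
        )
    if rng.random() < cfg.occlusion_low_contrast_weight:
        contrast = rng.uniform(0.0, cfg.occlusion_low_contrast_max)
    else:
        contrast = rng.uniform(0.0, cfg.occlusion_contrast_max)
    return SynthPatchParams(
        category="occlusion",
        contrast_target=contrast,
        blur_sigma=0.0,
        texture_seed_left=seed_l,
        texture_seed_right=seed_r,
        texture_similarity=rng.uniform(*cfg.occlusion_similarity_range),
        spectrum=spectrum,
    )


def make_dataset(
    n_per_class: int,
    seed: int,
    config: DatasetConfig = DatasetConfig(),
) -> Tuple[List[ImagePatch], pd.DataFrame]:
    """Generate a labeled dataset of synthetic patches plus its manifest.

    Patches are tagged with a category-pure ``pseudo_image_id`` (blocks of
    ``config.patches_per_image`` consecutive patches) so by-image
    cross-validation folds can be formed.
    """
    rng = np.random.default_rng(seed)
    patches: List[ImagePatch] = []
    rows = []
    for category in ("shadow", "occlusion"):
        for i in range(n_per_class):
            params = _sample_params(category, rng, config)
            patch = make_patch(params)
            image_id = f"{category}_{i // config.patches_per_image:04d}"
            patch.meta["pseudo_image_id"] = image_id
            patch.source_id = (image_id, i)
            patches.append(patch)
            rows.append(
                {
                    "patch_id": f"{category}_{i:06d}",
                    "category": category,
                    "pseudo_image_id": image_id,
                    "contrast_target": params.contrast_target,
                    "blur_sigma": params.blur_sigma,
                    "texture_similarity": params.texture_similarity,
                    "seed": params.texture_seed_left,
                }
            )
    return patches, pd.DataFrame(rows)


def make_pseudo_scene(
    seed: int,
    size: int = 128,
    n_edges: int = 4,
    n_annotators: int = 3,
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Grayscale pseudo-scene with per-annotator 1-pixel edge maps.

    Each edge is a straight segment crossing the scene; a soft luminance
    step is rendered across it so extracted patches carry a real contrast
    signal.  Edges are assigned to annotators cyclically.
    """
    if size < 100:
        raise ValueError("pseudo-scene size must be >= 100")
    rng = np.random.default_rng(seed)
    base = _noise_field(int(rng.integers(2**31 - 1)), size, TextureSpectrum(2.0))
    image = 0.5 + 0.1 * base
    maps = [np.zeros((size, size), dtype=bool) for _ in range(n_annotators)]
    yy, xx = np.mgrid[0:size, 0:size]
    for k in range(n_edges):
        # segment through a random interior point at a random angle
        cy, cx = rng.integers(size // 4, 3 * size // 4, size=2)
        theta = rng.uniform(0.0, np.pi)
        dy, dx = np.sin(theta), np.cos(theta)
        half = size  # long enough to cross the scene
        r0, c0 = int(cy - half * dy), int(cx - half * dx)
        r1, c1 = int(cy + half * dy), int(cx + half * dx)
        r0, c0 = np.clip(r0, 0, size - 1), np.clip(c0, 0, size - 1)
        r1, c1 = np.clip(r1, 0, size - 1), np.clip(c1, 0, size - 1)
        rr, cc = draw_line(r0, c0, r1, c1)
        maps[k % n_annotators][rr, cc] = True
        # soft step across the edge
        signed = (xx - cx) * dy - (yy - cy) * dx
        amp = rng.uniform(0.08, 0.2) * rng.choice([-1.0, 1.0])
        image = image + amp * np.tanh(signed / 1.5) / 2.0
    image = np.clip(image, 0.02, 0.98)
    return image, maps


def simulate_observers(
    response_probs: Sequence[float],
    n_observers: int,
    seed: int,
) -> SimulatedObserverSet:
    """Independent Bernoulli responses per observer and image."""
    probs = np.asarray(response_probs, dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("response probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    responses = (
        rng.random((n_observers, probs.size)) < probs[None, :]
    ).astype(int)
    return SimulatedObserverSet(
        n_observers=n_observers,
        response_probs=probs,
        responses=responses,
        seed=seed,
    )
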