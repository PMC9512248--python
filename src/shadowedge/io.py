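"""Reading and writing patch datasets, edge-labeled images and tables.

Patch datasets are stored as 16-bit grayscale PNGs plus a CSV manifest
(patch_id, category, pseudo_image_id, contrast_target, blur_sigma,
texture_similarity, seed, pixel_min, pixel_max).  Because synthetic
intensities can slightly leave [0, 1] at extreme contrast, each patch is
stored min-max scaled with its original range recorded in the manifest,
making the round trip lossless up to 16-bit quantization.

``load_labeled_database`` reads a directory layout of full-size images
plus per-annotator binary edge-map PNGs, matching the public
shadow/occlusion databases (grayscale or RGB images with hand-labeled
edge maps).
"""

from __future__ import annotations

import pathlib
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import ImagePatch
from .patch_extraction import LabeledEdgeImage, to_grayscale

__all__ = [
    "write_patch_dataset",
    "load_patch_dataset",
    "load_labeled_database",
    "read_image",
]

_U16 = 65535


def read_image(path) -> np.ndarray:
    """Grayscale float image in [0, 1] from a PNG/TIFF file."""
    arr = iio.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = to_grayscale(arr / arr.max() if arr.max() > 1 else arr)
        return arr
    info = np.iinfo(np.uint16) if arr.max() > 255 else np.iinfo(np.uint8)
    return arr / info.max


def write_patch_dataset(
    patches: Sequence[ImagePatch],
    manifest: pd.DataFrame,
    out_dir,
) -> pathlib.Path:
    """Write patches as 16-bit PNGs + manifest.csv (+ region-mask PNGs)."""
    out = pathlib.Path(out_dir)
    (out / "patches").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    mins, maxs = [], []
    for patch, pid in zip(patches, manifest["patch_id"]):
        lo = float(patch.pixels.min())
        hi = float(patch.pixels.max())
        span = hi - lo if hi > lo else 1.0
        quant = np.round((patch.pixels - lo) / span * _U16).astype(np.uint16)
        iio.imwrite(out / "patches" / f"{pid}.png", quant)
        if patch.region_masks is not None:
            m1, m2 = patch.region_masks
            combined = np.zeros(patch.pixels.shape, dtype=np.uint8)
            combined[m1] = 1
            combined[m2] = 2
            iio.imwrite(out / "masks" / f"{pid}.png", combined)
        mins.append(lo)
        maxs.append(hi)
    manifest["pixel_min"] = mins
    manifest["pixel_max"] = maxs
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def load_patch_dataset(
    in_dir,
) -> Tuple[List[ImagePatch], pd.DataFrame]:
    """Inverse of :func:`write_patch_dataset`."""
    root = pathlib.Path(in_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    patches: List[ImagePatch] = []
    for _, row in manifest.iterrows():
        quant = iio.imread(root / "patches" / f"{row.patch_id}.png")
        lo, hi = float(row.pixel_min), float(row.pixel_max)
        span = hi - lo if hi > lo else 1.0
        pixels = quant.astype(float) / _U16 * span + lo
        mask_path = root / "masks" / f"{row.patch_id}.png"
        region_masks = edge_mask = None
        if mask_path.exists():
            combined = iio.imread(mask_path)
            region_masks = (combined == 1, combined == 2)
            edge_mask = combined == 0
        patches.append(
            ImagePatch(
                pixels=pixels,
                region_masks=region_masks,
                edge_mask=edge_mask,
                aligned=True,
                category=row.category if "category" in row else None,
            )
        )
    return patches, manifest


def load_labeled_database(
    images_dir,
    labels_dir,
    category: Optional[str] = None,
) -> List[LabeledEdgeImage]:
    """Load images with per-annotator edge maps.

    Layout: ``images_dir/<name>.png`` and
    ``labels_dir/<name>_<annotator>.png`` (any number of annotators,
    nonzero pixels = edge).
    """
    images_dir = pathlib.Path(images_dir)
    labels_dir = pathlib.Path(labels_dir)
    out: List[LabeledEdgeImage] = []
    for img_path in sorted(images_dir.glob("*.png")):
        name = img_path.stem
        maps = [
            iio.imread(p) > 0
            for p in sorted(labels_dir.glob(f"{name}_*.png"))
        ]
        if not maps:
            continue
        out.append(
            LabeledEdgeImage(
                image=read_image(img_path),
                edge_maps=maps,
                category=category,
                name=name,
            )
        )
    return out
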