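"""Extract, vet and align edge-centered patches from labeled images.

A candidate 40x40 patch centered on a labeled edge pixel is accepted only
if the composite (all-annotator) edge map inside it forms a single
connected path dividing the patch into exactly two regions, the smaller
of which holds at least 35% of the pixels.  This excludes T-junctions and
highly convex edges.  Accepted patches are then canonicalized: rotated so
the edge's principal axis is vertical and mirrored, if necessary, so the
left side is darker than the right.

Connectivity conventions: 8-connectivity for the (thin) edge path,
4-connectivity for the background regions, the standard duality that
prevents background regions leaking through diagonal edge pixels.
Coordinates are 0-based, row-major, top-left origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .containers import ImagePatch

__all__ = [
    "LabeledEdgeImage",
    "to_grayscale",
    "sample_edge_centers",
    "accept_patch",
    "align_patch",
    "extract_patches",
    "MIN_REGION_FRACTION",
]

MIN_REGION_FRACTION = 0.35

GRAY_COEFFS = np.array([0.2989, 0.5870, 0.1140])

_EDGE_STRUCTURE = np.ones((3, 3), dtype=bool)  # 8-connectivity
_REGION_STRUCTURE = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class LabeledEdgeImage:
    """A grayscale image plus one binary edge map per annotator."""

    image: np.ndarray
    edge_maps: List[np.ndarray]
    category: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.edge_maps = [np.asarray(m, dtype=bool) for m in self.edge_maps]
        for m in self.edge_maps:
            if m.shape != self.image.shape[:2]:
                raise ValueError("edge maps must match the image shape")

    @property
    def composite_map(self) -> np.ndarray:
        """Pixelwise union of all annotators' edge maps."""
        out = np.zeros(self.image.shape[:2], dtype=bool)
        for m in self.edge_maps:
            out |= m
        return out


def to_grayscale(rgb_pixels: np.ndarray) -> np.ndarray:
    """Weighted sum I = 0.2989 R + 0.5870 G + 0.1140 B of linearized RGB."""
    rgb = np.asarray(rgb_pixels, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected an array with a trailing RGB axis")
    if np.any(rgb < 0):
        raise ValueError("linearized RGB values must be non-negative")
    return rgb @ GRAY_COEFFS


def sample_edge_centers(
    labeled: LabeledEdgeImage,
    n: int,
    seed: int,
) -> List[Tuple[int, int]]:
    """Draw edge-pixel centers, cycling through annotators per draw.

    Each draw takes a uniformly random not-yet-used labeled pixel from the
    current annotator's map (annotators visited in cyclic order); an
    annotator's pixels are replenished (reshuffled) if exhausted.
    """
    per_annotator = []
    rng = np.random.default_rng(seed)
    for m in labeled.edge_maps:
        coords = np.argwhere(m)
        per_annotator.append(coords)
    if all(len(c) == 0 for c in per_annotator):
        warnings.warn("no labeled edge pixels; returning an empty list")
        return []
    queues: List[List[int]] = [[] for _ in per_annotator]
    centers: List[Tuple[int, int]] = []
    k = 0
    drawn = 0
    while drawn < n:
        a = k % len(per_annotator)
        k += 1
        coords = per_annotator[a]
        if len(coords) == 0:
            continue
        if not queues[a]:
            queues[a] = list(rng.permutation(len(coords)))
        i = queues[a].pop()
        centers.append((int(coords[i, 0]), int(coords[i, 1])))
        drawn += 1
    return centers


def accept_patch(
    composite_patch_map: np.ndarray,
) -> Tuple[bool, Optional[Tuple[np.ndarray, np.ndarray]]]:
    """Vet a candidate patch by its composite edge map.

    Accepted iff the edge pixels form one 8-connected component whose
    removal leaves exactly two 4-connected background regions, the smaller
    of which comprises at least 35% of all patch pixels.  Returns the two
    region masks on acceptance.
    """
    edge = np.asarray(composite_patch_map, dtype=bool)
    if edge.sum() == 0:
        return False, None
    _, n_edge = ndimage.label(edge, structure=_EDGE_STRUCTURE)
    if n_edge != 1:
        return False, None
    background, n_regions = ndimage.label(~edge, structure=_REGION_STRUCTURE)
    if n_regions != 2:
        return False, None
    total = edge.size
    mask1 = background == 1
    mask2 = background == 2
    if min(mask1.sum(), mask2.sum()) / total < MIN_REGION_FRACTION:
        return False, None
    return True, (mask1, mask2)


def _edge_axis_angle(edge_mask: np.ndarray) -> float:
    """Angle (radians from vertical) of the edge path's principal axis."""
    coords = np.argwhere(edge_mask).astype(float)
    if len(coords) < 2:
        raise ValueError("degenerate edge: orientation undefined")
    coords -= coords.mean(axis=0)
    cov = coords.T @ coords
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]  # (d_row, d_col) of the principal axis
    # angle from the vertical (row) axis, in (-pi/2, pi/2]
    angle = np.arctan2(v[1], v[0])
    if angle > np.pi / 2:
        angle -= np.pi
    elif angle <= -np.pi / 2:
        angle += np.pi
    return float(angle)


def align_patch(patch: ImagePatch) -> ImagePatch:
    """Canonicalize a patch: vertical edge, darker side on the left.

    The patch is rotated so the principal axis of its edge path is
    vertical (bilinear interpolation for pixels; the partition is
    re-derived by rotating soft region/edge indicators and assigning each
    pixel to the strongest one, so the three masks always partition the
    patch).  If a larger source window is attached, rotation happens in
    the window and the center is re-cropped, avoiding out-of-bounds
    pixels.  Finally the patch is mirrored left-right if its left half is
    brighter than its right half.
    """
    if patch.region_masks is None or patch.edge_mask is None:
        raise ValueError("align_patch requires region masks and an edge mask")
    size = patch.size
    angle = _edge_axis_angle(patch.edge_mask)
    pixels = patch.pixels
    masks = [
        patch.region_masks[0].astype(float),
        patch.region_masks[1].astype(float),
        patch.edge_mask.astype(float),
    ]
    if abs(angle) > 1e-9:
        degrees = np.degrees(angle)

        def _rot(arr: np.ndarray, order: int) -> np.ndarray:
            return ndimage.rotate(
                arr, degrees, reshape=False, order=order, mode="nearest"
            )

        if patch.window is not None:
            win = np.asarray(patch.window, dtype=float)
            rotated = _rot(win, 1)
            off = (win.shape[0] - size) // 2
            pixels = rotated[off : off + size, off : off + size]
        else:
            pixels = _rot(pixels, 1)
        soft = [_rot(m, 1) for m in masks]
        choice = np.argmax(np.stack(soft), axis=0)
        masks = [(choice == i).astype(float) for i in range(3)]

    region_a = masks[0] > 0.5
    region_b = masks[1] > 0.5
    edge = masks[2] > 0.5

    half = size // 2
    if pixels[:, :half].mean() > pixels[:, half:].mean():
        pixels = pixels[:, ::-1]
        region_a = region_a[:, ::-1]
        region_b = region_b[:, ::-1]
        edge = edge[:, ::-1]

    return ImagePatch(
        pixels=np.ascontiguousarray(pixels),
        region_masks=(region_a, region_b),
        edge_mask=edge,
        aligned=True,
        category=patch.category,
        source_id=patch.source_id,
        meta=dict(patch.meta),
    )


def extract_patches(
    labeled: LabeledEdgeImage,
    n: int,
    seed: int,
    patch_size: int = 40,
    window_size: int = 57,
    align: bool = True,
) -> List[ImagePatch]:
    """Sample, vet and (optionally) align patches from a labeled image.

    ``window_size`` controls the larger source crop kept with each patch
    so alignment rotation never samples out of bounds (57 covers the
    diagonal of a 40x40 patch).
    """
    gray = labeled.image
    if gray.ndim == 3:
        gray = to_grayscale(gray)
    composite = labeled.composite_map
    half = patch_size // 2
    whalf = window_size // 2
    centers = sample_edge_centers(labeled, n, seed)
    out: List[ImagePatch] = []
    for r, c in centers:
        if (
            r - half < 0
            or c - half < 0
            or r - half + patch_size > gray.shape[0]
            or c - half + patch_size > gray.shape[1]
        ):
            continue
        sl = np.s_[r - half : r - half + patch_size,
                   c - half : c - half + patch_size]
        ok, masks = accept_patch(composite[sl])
        if not ok:
            continue
        window = None
        if (
            r - whalf >= 0
            and c - whalf >= 0
            and r - whalf + window_size <= gray.shape[0]
            and c - whalf + window_size <= gray.shape[1]
        ):
            window = gray[
                r - whalf : r - whalf + window_size,
                c - whalf : c - whalf + window_size,
            ].copy()
        patch = ImagePatch(
            pixels=gray[sl].copy(),
            region_masks=masks,
            edge_mask=composite[sl].copy(),
            aligned=False,
            category=labeled.category,
            source_id=(labeled.name, (r, c)),
            window=window,
        )
        out.append(align_patch(patch) if align else patch)
    return out
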