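"""Core in-memory containers shared across the package.

An :class:`ImagePatch` is a square grayscale patch centered on an edge,
optionally carrying a two-region partition (the surfaces / lit-shaded
regions flanking the edge), a one-pixel-wide edge-path mask, and a larger
source window so rotation during alignment never samples out of bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = ["ImagePatch", "PatchFeatures"]


@dataclass
class ImagePatch:
    """Square grayscale patch, optionally partitioned into two regions.

    Parameters
    ----------
    pixels
        2-D float array of linearized luminance values, typically in [0, 1].
    region_masks
        Two disjoint boolean masks covering all non-edge pixels, or None.
    edge_mask
        Boolean mask of the edge path, or None.
    aligned
        True if the edge is vertical with the darker side on the left.
    category
        ``"shadow"`` or ``"occlusion"`` when the ground truth is known.
    source_id
        Identifier of the source image plus (row, col) of the patch center
        (0-based, top-left origin).
    window
        Optional larger array the patch was cropped from (centered), used
        to avoid out-of-bounds pixels when the patch is rotated.
    """

    pixels: np.ndarray
    region_masks: Optional[Tuple[np.ndarray, np.ndarray]] = None
    edge_mask: Optional[np.ndarray] = None
    aligned: bool = False
    category: Optional[str] = None
    source_id: Optional[tuple] = None
    window: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("patch pixels must be a square 2-D array")
        if self.region_masks is not None:
            a, b = self.region_masks
            a = np.asarray(a, dtype=bool)
            b = np.asarray(b, dtype=bool)
            if a.shape != self.pixels.shape or b.shape != self.pixels.shape:
                raise ValueError("region masks must match patch shape")
            if np.any(a & b):
                raise ValueError("region masks must be disjoint")
            self.region_masks = (a, b)
        if self.edge_mask is not None:
            self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
            if self.edge_mask.shape != self.pixels.shape:
                raise ValueError("edge mask must match patch shape")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class PatchFeatures:
    """Per-patch contrast and spectral statistics.

    c_rms : RMS contrast sigma/mu (dimensionless, >= 0).
    c_m   : Michelson contrast |mu2 - mu1| / (mu2 + mu1), in [0, 1).
    pi_h  : proportion of spectral power above 10 cycles/image, in [0, 1].
    """

    c_rms: float
    c_m: float
    pi_h: float
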