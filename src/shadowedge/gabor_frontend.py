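"""Multi-scale log-Gabor filter bank front-end (V1 simple-cell model).

The bank covers 3 spatial scales (8, 16, 32 pixel support), 6 orientations,
2 phases (even/odd quadrature pair) and 2 contrast polarities (+/-), for 72
filters in total (24 per scale).  Each filter is constructed in the
frequency domain as a log-Gaussian radial profile (zero DC by construction)
times a Gaussian angular profile centered on one orientation half-plane;
the inverse transform yields the even (real part) and odd (imaginary part)
spatial kernels in quadrature.  The radial width is set so the
half-magnitude spatial-frequency bandwidth is 1.5 octaves, typical of V1
neurons.  Polarity is a global sign flip of the kernel.

``apply_frontend`` removes the patch mean (the filters have no DC
response, so only zero-padding border effects would otherwise leak the
mean in), convolves with every filter ('same' output, zero padding),
half-wave rectifies each polarity, and MAX-pools
over non-overlapping 8x8 blocks down to 5x5, giving a 1800-dimensional
non-negative feature vector with layout
(scale, orientation, phase, polarity, pool_row, pool_col).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "GaborBankSpec",
    "GaborFilter",
    "build_bank",
    "measure_bandwidth",
    "apply_frontend",
    "apply_frontend_batch",
    "linear_responses",
    "linear_adjoint",
    "pool_responses",
    "N_FEATURES",
]

N_FEATURES = 1800


@dataclass(frozen=True)
class GaborBankSpec:
    """Definition of the fixed filter bank.

    ``scales`` are both the square kernel supports (in pixels) and the
    center wavelengths (pixels/cycle).  ``bandwidth_octaves`` is the
    half-magnitude spatial-frequency bandwidth of the radial profile.
    """

    scales: Tuple[int, ...] = (8, 16, 32)
    n_orientations: int = 6
    bandwidth_octaves: float = 1.5
    pool_grid: int = 5
    patch_size: int = 40

    @property
    def n_filters(self) -> int:
        # scales x orientations x 2 phases x 2 polarities
        return len(self.scales) * self.n_orientations * 4

    @property
    def n_features(self) -> int:
        return self.n_filters * self.pool_grid**2

    @property
    def orientations(self) -> np.ndarray:
        """Equally spaced in [0, pi), starting at vertical (theta = 0)."""
        return np.arange(self.n_orientations) * np.pi / self.n_orientations


@dataclass(frozen=True)
class GaborFilter:
    """One member of the bank: a spatial kernel plus its index labels."""

    kernel: np.ndarray
    scale: int
    orientation: float
    phase: str  # "even" | "odd"
    polarity: int  # +1 | -1


def _sigma_on_f(bandwidth_octaves: float) -> float:
    """Log-Gaussian width ratio giving the requested octave bandwidth.

    For G(f) = exp(-(ln(f/f0))^2 / (2 ln(s)^2)) the half-magnitude octave
    bandwidth is 2*sqrt(2 ln 2)*|ln s| / ln 2; invert for s < 1.
    """
    ln2 = np.log(2.0)
    return float(np.exp(-bandwidth_octaves * ln2 / (2.0 * np.sqrt(2.0 * ln2))))


def _radial_profile(f: np.ndarray, f0: float, sigma_on_f: float) -> np.ndarray:
    out = np.zeros_like(f)
    nz = f > 0
    out[nz] = np.exp(
        -(np.log(f[nz] / f0) ** 2) / (2.0 * np.log(sigma_on_f) ** 2)
    )
    return out


def _complex_kernel(
    size: int, orientation: float, bandwidth_octaves: float
) -> np.ndarray:
    """Spatial-domain complex log-Gabor kernel on a size x size grid.

    The frequency response is restricted to the half-plane around
    ``orientation`` so that real/imag spatial parts form a quadrature pair.
    Orientation 0 means a vertically oriented filter (horizontal frequency
    axis), matching the aligned-edge convention.
    """
    f1 = np.fft.fftfreq(size)  # cycles/pixel
    fx, fy = np.meshgrid(f1, f1)
    f = np.sqrt(fx**2 + fy**2)
    radial = _radial_profile(f, 1.0 / size, _sigma_on_f(bandwidth_octaves))

    # angle of each frequency point; orientation 0 -> energy along fx
    phi = np.arctan2(fy, fx)
    dphi = np.angle(np.exp(1j * (phi - orientation)))
    sigma_theta = np.pi / 12.0  # half the orientation spacing
    angular = np.exp(-(dphi**2) / (2.0 * sigma_theta**2))

    spectrum = radial * angular
    kernel = np.fft.fftshift(np.fft.ifft2(spectrum))
    return kernel


def _normalize(k: np.ndarray) -> np.ndarray:
    k = k - k.mean()  # enforce exactly zero DC on the discrete grid
    norm = np.linalg.norm(k)
    return k / norm


def build_bank(spec: GaborBankSpec = GaborBankSpec()) -> List[GaborFilter]:
    """Construct the 72 spatial-domain filters of the bank.

    Ordering is (scale, orientation, phase=even/odd, polarity=+/-), the
    same ordering used by the feature-vector layout.
    """
    filters: List[GaborFilter] = []
    for size in spec.scales:
        for theta in spec.orientations:
            ck = _complex_kernel(size, float(theta), spec.bandwidth_octaves)
            even = _normalize(np.real(ck))
            odd = _normalize(np.imag(ck))
            for phase, kern in (("even", even), ("odd", odd)):
                for polarity in (+1, -1):
                    filters.append(
                        GaborFilter(
                            kernel=polarity * kern,
                            scale=size,
                            orientation=float(theta),
                            phase=phase,
                            polarity=polarity,
                        )
                    )
    return filters


def measure_bandwidth(
    scale: int, bandwidth_octaves: float = 1.5, n: int = 4096
) -> float:
    """Numerically measured half-magnitude bandwidth (octaves).

    Evaluates the radial frequency profile on a dense log-spaced grid and
    returns log2(f_hi / f_lo) where the profile crosses half its maximum.
    """
    f0 = 1.0 / scale
    f = np.geomspace(f0 / 16, min(0.5, f0 * 16), n)
    g = _radial_profile(f, f0, _sigma_on_f(bandwidth_octaves))
    above = np.where(g >= 0.5)[0]
    f_lo, f_hi = f[above[0]], f[above[-1]]
    return float(np.log2(f_hi / f_lo))


def _unique_linear_filters(
    bank: Sequence[GaborFilter],
) -> List[GaborFilter]:
    """The +1-polarity filters; the -1 ones are their sign flips."""
    return [flt for flt in bank if flt.polarity == +1]


def linear_responses(
    patches: np.ndarray, bank: Sequence[GaborFilter]
) -> np.ndarray:
    """'Same'-size zero-padded convolution with each unique linear filter.

    Parameters
    ----------
    patches
        (N, H, W) stack of patches (or (H, W) for a single one).
    bank
        Full 72-filter bank; only the 36 +polarity kernels are convolved,
        since -polarity responses are sign flips.

    Returns
    -------
    (N, 36, H, W) array of linear filter outputs.
    """
    patches = np.asarray(patches, dtype=float)
    single = patches.ndim == 2
    if single:
        patches = patches[None]
    lin = _unique_linear_filters(bank)
    H, W = patches.shape[1:]
    # group filters by kernel size so fftconvolve can broadcast per group;
    # convolve 'full' and crop to 'same' at offset (S-1)//2 by hand, since
    # scipy's mode='same' crops to in1's shape and defeats the broadcast
    out = np.empty((patches.shape[0], len(lin), H, W))
    sizes = sorted({f.kernel.shape[0] for f in lin})
    for size in sizes:
        idx = [i for i, f in enumerate(lin) if f.kernel.shape[0] == size]
        kernels = np.stack([lin[i].kernel for i in idx])
        resp = fftconvolve(
            patches[:, None, :, :], kernels[None, :, :, :], mode="full",
            axes=(2, 3),
        )
        a = (size - 1) // 2
        out[:, idx] = resp[:, :, a : a + H, a : a + W]
    return out


def linear_adjoint(
    grads: np.ndarray, bank: Sequence[GaborFilter]
) -> np.ndarray:
    """Adjoint of :func:`linear_responses` (for gradient backpropagation).

    ``grads`` is (36, H, W): the gradient with respect to each linear
    response map; returns the (H, W) gradient with respect to the patch.
    For 'same' convolution cropped from the full output at offset
    (S-1)//2, the adjoint is full convolution with the doubly flipped
    kernel cropped at offset S//2.
    """
    lin = _unique_linear_filters(bank)
    H, W = grads.shape[1:]
    gx = np.zeros((H, W))
    for g, flt in zip(grads, lin):
        k = flt.kernel[::-1, ::-1]
        S = k.shape[0]
        full = fftconvolve(g, k, mode="full")
        b = S // 2
        gx += full[b : b + H, b : b + W]
    return gx


def pool_responses(
    linear: np.ndarray, pool_grid: int = 5
) -> Tuple[np.ndarray, np.ndarray]:
    """Rectify both polarities and MAX-pool to a pool_grid x pool_grid map.

    Parameters
    ----------
    linear
        (N, F, H, W) linear responses (F unique filters).

    Returns
    -------
    features : (N, F*4*pool_grid**2) with layout
        (filter, phase-implicit-in-F, polarity, pool_row, pool_col); the
        caller's F axis already carries (scale, orientation, phase).
    argmax : (N, F, 2, pool_grid, pool_grid) flat within-block index of
        each pooled maximum (for backpropagation).
    """
    N, F, H, W = linear.shape
    block = H // pool_grid
    r = linear.reshape(N, F, pool_grid, block, pool_grid, block)
    blocks = r.transpose(0, 1, 2, 4, 3, 5).reshape(
        N, F, pool_grid, pool_grid, block * block
    )
    plus = np.maximum(blocks, 0.0)
    minus = np.maximum(-blocks, 0.0)
    feats = np.empty((N, F, 2, pool_grid, pool_grid))
    arg = np.empty((N, F, 2, pool_grid, pool_grid), dtype=int)
    feats[:, :, 0] = plus.max(axis=-1)
    arg[:, :, 0] = plus.argmax(axis=-1)
    feats[:, :, 1] = minus.max(axis=-1)
    arg[:, :, 1] = minus.argmax(axis=-1)
    return feats.reshape(N, -1), arg


def apply_frontend(
    patch: np.ndarray,
    bank: Sequence[GaborFilter],
    spec: GaborBankSpec = GaborBankSpec(),
) -> np.ndarray:
    """Feature vector (length 1800) for a single aligned patch."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (spec.patch_size, spec.patch_size):
        raise ValueError(
            f"expected a {spec.patch_size}x{spec.patch_size} patch, "
            f"got {patch.shape}"
        )
    return apply_frontend_batch(patch[None], bank, spec)[0]


def apply_frontend_batch(
    patches: np.ndarray,
    bank: Sequence[GaborFilter],
    spec: GaborBankSpec = GaborBankSpec(),
    chunk: int = 256,
) -> np.ndarray:
    """Feature matrix (N, 1800) for a stack of aligned patches."""
    patches = np.asarray(patches, dtype=float)
    if patches.shape[1:] != (spec.patch_size, spec.patch_size):
        raise ValueError("patches must be N x 40 x 40 (per the bank spec)")
    patches = patches - patches.mean(axis=(1, 2), keepdims=True)
    out = np.empty((patches.shape[0], spec.n_features))
    for start in range(0, patches.shape[0], chunk):
        batch = patches[start : start + chunk]
        lin = linear_responses(batch, bank)
        feats, _ = pool_responses(lin, spec.pool_grid)
        out[start : start + batch.shape[0]] = feats
    return out


def frontend_forward_cache(
    patch: np.ndarray, bank: Sequence[GaborFilter], spec: GaborBankSpec
) -> dict:
    """Forward pass keeping what backpropagation needs."""
    patch = patch - patch.mean()
    lin = linear_responses(patch[None], bank)
    feats, arg = pool_responses(lin, spec.pool_grid)
    return {"linear": lin[0], "features": feats[0], "argmax": arg[0]}


def frontend_backward(
    grad_features: np.ndarray,
    cache: dict,
    bank: Sequence[GaborFilter],
    spec: GaborBankSpec,
) -> np.ndarray:
    """Gradient of the patch given a gradient on the 1800 features."""
    lin = cache["linear"]  # (F, H, W)
    F, H, W = lin.shape
    pg = spec.pool_grid
    block = H // pg
    g = grad_features.reshape(F, 2, pg, pg)
    arg = cache["argmax"]  # (F, 2, pg, pg)
    feats = cache["features"].reshape(F, 2, pg, pg)
    grad_lin = np.zeros_like(lin)
    for f in range(F):
        for pol in range(2):
            sign = 1.0 if pol == 0 else -1.0
            for i in range(pg):
                for j in range(pg):
                    if feats[f, pol, i, j] <= 0.0:
                        continue  # rectified max is 0: no gradient
                    a = arg[f, pol, i, j]
                    r, c = divmod(a, block)
                    grad_lin[f, i * block + r, j * block + c] += sign * g[
                        f, pol, i, j
                    ]
    gx = linear_adjoint(grad_lin, bank)
    return gx - gx.mean()  # adjoint of the de-meaning step
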