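"""Per-patch contrast and spectral statistics, and group-level comparisons.

Three statistics summarize an edge-centered patch:

* RMS contrast ``c_RMS = sigma / mu`` (population standard deviation of the
  pixel intensities over their mean),
* Michelson contrast ``c_M = |mu2 - mu1| / (mu2 + mu1)`` computed from the
  mean intensities of the two regions flanking the edge,
* ``pi_h``: the proportion of spectral power above 10 cycles/image, after
  removing the mean and normalizing total energy.  For 40x40 patches the
  Nyquist limit is 20 cycles/image.

Shadow edges tend to carry less high-frequency power than occlusion edges
because of penumbral blur, which is what ``pi_h`` quantifies.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .containers import ImagePatch

__all__ = [
    "rms_contrast",
    "michelson_contrast",
    "high_freq_proportion",
    "rotational_average_amplitude",
    "radial_frequency_map",
    "compare_groups",
]

HIGH_FREQ_CUTOFF = 10.0  # cycles/image


def _pixels(patch: Union[ImagePatch, np.ndarray]) -> np.ndarray:
    if isinstance(patch, ImagePatch):
        return patch.pixels
    return np.asarray(patch, dtype=float)


def rms_contrast(patch: Union[ImagePatch, np.ndarray]) -> float:
    """RMS contrast sigma/mu (population standard deviation)."""
    x = _pixels(patch)
    mu = x.mean()
    if mu <= 0:
        raise ValueError("RMS contrast requires a positive mean intensity")
    return float(x.std() / mu)


def michelson_contrast(
    patch: Union[ImagePatch, np.ndarray],
    region_masks: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Michelson contrast |mu2 - mu1| / (mu2 + mu1) of the two regions."""
    x = _pixels(patch)
    if region_masks is None:
        if not isinstance(patch, ImagePatch) or patch.region_masks is None:
            raise ValueError("michelson_contrast requires a two-region partition")
        region_masks = patch.region_masks
    m1, m2 = region_masks
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError("both regions must be non-empty")
    mu1 = x[m1].mean()
    mu2 = x[m2].mean()
    if mu1 + mu2 <= 0:
        raise ValueError("region means must have a positive sum")
    return float(abs(mu2 - mu1) / (mu2 + mu1))


def radial_frequency_map(size: int) -> np.ndarray:
    """Integer radial frequency (cycles/image) of each DFT grid point.

    Radius is ``round(sqrt(fx^2 + fy^2))`` with fx, fy in cycles/image,
    in the unshifted (numpy fft) layout.
    """
    f = np.fft.fftfreq(size) * size
    fx, fy = np.meshgrid(f, f)
    return np.round(np.sqrt(fx**2 + fy**2)).astype(int)


def _normalized_power(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    energy = np.sum(x**2)
    if energy <= 0:
        raise ValueError("constant patch: spectral statistics undefined")
    x = x / np.sqrt(energy)
    return np.abs(np.fft.fft2(x)) ** 2


def high_freq_proportion(
    patch: Union[ImagePatch, np.ndarray],
    cutoff: float = HIGH_FREQ_CUTOFF,
    include_dc: bool = False,
) -> float:
    """Proportion pi_h of spectral power above ``cutoff`` cycles/image.

    The patch is de-meaned and energy-normalized, its 2-D power spectrum is
    binned by rounded integer radial frequency, and the power in bins above
    the cutoff is divided by total power.  The DC bin is excluded from the
    denominator by default (the patch is zero-mean, so it is ~0 anyway);
    ``include_dc=True`` keeps it.
    """
    x = _pixels(patch)
    power = _normalized_power(x)
    r = radial_frequency_map(x.shape[0])
    denom_mask = np.ones_like(power, dtype=bool) if include_dc else (r > 0)
    num = power[r > cutoff].sum()
    den = power[denom_mask].sum()
    return float(num / den)


def rotational_average_amplitude(
    patch: Union[ImagePatch, np.ndarray]
) -> np.ndarray:
    """Mean amplitude per integer radial-frequency bin, 1..Nyquist.

    For a 40x40 patch the returned curve has 20 bins (Nyquist is 20
    cycles/image).
    """
    x = _pixels(patch)
    power = _normalized_power(x)
    amplitude = np.sqrt(power)
    r = radial_frequency_map(x.shape[0])
    nyquist = x.shape[0] // 2
    curve = np.empty(nyquist)
    for k in range(1, nyquist + 1):
        curve[k - 1] = amplitude[r == k].mean()
    return curve


def compare_groups(
    x_values: Sequence[float], y_values: Sequence[float]
) -> dict:
    """Distribution-level comparison of two feature samples.

    Returns the group medians, the two-sided Wilcoxon rank-sum
    (Mann-Whitney) p-value for a median difference (exact for small
    samples without ties), and Pearson/Spearman correlations of the paired
    values when the groups have equal length.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    mw = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    out = {
        "median_x": float(np.median(x)),
        "median_y": float(np.median(y)),
        "rank_sum_p": float(mw.pvalue),
    }
    if x.size == y.size:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("correlation undefined for constant inputs")
        out["pearson_r"] = float(stats.pearsonr(x, y).statistic)
        out["spearman_rho"] = float(stats.spearmanr(x, y).statistic)
    return out
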