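"""Renyi-entropy binarization and foreground dilation.

Each preprocessed channel plane is binarized by maximum-entropy
thresholding of its intensity histogram using the Renyi entropy of order
``alpha``.  For a class distribution ``p`` (histogram counts of one side
of the cut, normalized to sum to 1) the Renyi entropy is

    H_alpha(p) = ln(sum_i p_i^alpha) / (1 - alpha),   alpha > 0, alpha != 1,

which converges to the Shannon entropy as alpha -> 1.  The threshold is
the cut maximizing the sum of the background-class and foreground-class
entropies; ties break toward the lower cut.  A single order with
alpha = 2 is used by default (configurable), rather than the three-order
combination rule of some ImageJ ports.

Positive pixels are then dilated with a 3x3 square structuring element —
one pixel becomes a 9-pixel block — to absorb the sub-resolution
localization error of the low-magnification survey and so protect the
recall of the downstream overlap detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import DegenerateInputError


@dataclass(frozen=True)
class ThresholdParams:
    """Renyi-threshold configuration.

    alpha is the entropy order (> 0, != 1); n_bins the number of histogram
    bins spanning the per-plane min-max range (256 by default, the 8-bit
    equivalent).  Dilation always uses a 3x3 square.
    """

    alpha: float = 2.0
    n_bins: int = 256
    noise_floor_sigmas: float = 3.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha == 1:
            raise ValueError("alpha must be > 0 and != 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.noise_floor_sigmas < 0:
            raise ValueError("noise_floor_sigmas must be >= 0")


@dataclass
class BinaryMask:
    """Thresholded foreground for one channel of one section."""

    section: int
    channel: str
    pixels: np.ndarray  # boolean grid, same shape as the source plane
    threshold: float = float("nan")  # intensity threshold actually applied
    dilated: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)


def renyi_threshold(histogram: np.ndarray, alpha: float = 2.0) -> int:
    """Maximum-Renyi-entropy threshold of a histogram.

    Returns the bin index ``t`` maximizing
    ``H_alpha(bins <= t) + H_alpha(bins > t)`` over all cuts that leave
    both classes with nonzero mass, where each class distribution is the
    histogram slice normalized to sum to 1 and zero-count bins contribute
    nothing to ``sum p_i**alpha``.  Ties break toward the lower index.

    The criterion is evaluated for all cuts at once via cumulative sums:
    for class weight ``W(t)`` and power sum ``S(t) = sum h_i**alpha``,
    ``H_alpha = ln(S / W**alpha) / (1 - alpha)``.

    Raises
    ------
    DegenerateInputError
        If fewer than two bins are occupied (no valid cut exists).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size == 0:
        raise ValueError("histogram must be a nonempty 1-D array of counts")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be nonnegative")
    occupied = np.flatnonzero(hist > 0)
    if occupied.size < 2:
        raise DegenerateInputError("histogram has fewer than 2 occupied bins")

    cum_w = np.cumsum(hist)
    cum_s = np.cumsum(hist**alpha)
    total_w, total_s = cum_w[-1], cum_s[-1]
    # Valid cuts leave at least one occupied bin on each side.
    ts = np.arange(occupied[0], occupied[-1])
    w_b, s_b = cum_w[ts], cum_s[ts]
    w_f, s_f = total_w - w_b, total_s - s_b
    h_b = (np.log(s_b) - alpha * np.log(w_b)) / (1.0 - alpha)
    h_f = (np.log(s_f) - alpha * np.log(w_f)) / (1.0 - alpha)
    h = h_b + h_f
    # Lowest cut within a small tolerance of the maximum, so mathematical
    # ties (e.g. symmetric histograms) resolve to the lower threshold
    # regardless of floating-point evaluation order.
    m = h.max()
    eps = 1e-9 * max(1.0, abs(m))
    return int(ts[np.argmax(h >= m - eps)])


def binarize_channel(
    plane: np.ndarray,
    params: ThresholdParams,
    *,
    section: int = 0,
    channel: str = "",
) -> BinaryMask:
    """Binarize a preprocessed plane by Renyi-entropy thresholding.

    The histogram spans the per-plane min-max range, so negative values
    left by background flattening are representable without clipping, and
    the mask is invariant to adding a constant to the plane.

    The entropy criterion assumes the histogram mixes a background and a
    foreground mode; on a structure-free plane it would simply balance the
    noise distribution.  A noise floor therefore backstops the cut: it can
    never drop below ``median + noise_floor_sigmas * robust sd`` (robust
    sd = 1.4826 * MAD), so empty planes yield only the extreme noise tail
    instead of a third of their pixels.  Set ``noise_floor_sigmas = 0`` to
    disable.
    """
    plane = np.asarray(plane, dtype=np.float64)
    lo, hi = float(plane.min()), float(plane.max())
    if lo == hi:
        raise DegenerateInputError("constant plane cannot be thresholded")
    hist, edges = np.histogram(plane, bins=params.n_bins, range=(lo, hi))
    t = renyi_threshold(hist, params.alpha)
    cut = float(edges[t + 1])
    if params.noise_floor_sigmas > 0:
        med = float(np.median(plane))
        robust_sd = 1.4826 * float(np.median(np.abs(plane - med)))
        cut = max(cut, med + params.noise_floor_sigmas * robust_sd)
    return BinaryMask(
        section=section, channel=channel, pixels=plane > cut, threshold=cut
    )


_SQUARE_3X3 = np.ones((3, 3), dtype=bool)


def dilate_mask(mask: BinaryMask) -> BinaryMask:
    """Dilate with a 3x3 square: each positive pixel becomes a 9-pixel block."""
    if mask.pixels.ndim != 2:
        raise ValueError("mask must be 2-D")
    dilated = ndimage.binary_dilation(mask.pixels, structure=_SQUARE_3X3)
    return BinaryMask(
        section=mask.section,
        channel=mask.channel,
        pixels=dilated,
        threshold=mask.threshold,
        dilated=True,
    )
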