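"""Brightness normalization and background flattening of survey planes.

Stitched low-magnification mosaics carry two nuisance signals that must be
cancelled before any histogram-based binarization: multiplicative
brightness differences between camera tiles, and a slowly varying
background (uneven illumination, resin autofluorescence).  The pipeline
removes them in a fixed order:

1. :func:`normalize_plane` rescales each section plane to a common target
   mean ``mu`` and standard deviation ``sigma`` via the affine map
   ``Img / std(Img) * sigma - mean(Img / std(Img) * sigma) + mu``.
2. :func:`flatten_background` subtracts a Gaussian-blur estimate of the
   local brightness tendency, leaving punctate and tubular foreground on
   an approximately zero-mean background.

Both steps are affine in the pixel values, so rank ordering is preserved
and downstream entropy thresholding sees an undistorted histogram shape.
Negative values after flattening are retained; the thresholder shifts its
histogram rather than clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate for the operation (e.g. a
    constant plane, whose standard deviation is zero)."""


@dataclass(frozen=True)
class NormalizationParams:
    """Targets for per-plane brightness normalization.

    target_mean and target_sd are in intensity units; background_sigma is
    the Gaussian scale (pixels) used for background estimation and must be
    large compared to the structures of interest.
    """

    target_mean: float = 100.0
    target_sd: float = 20.0
    background_sigma: float = 50.0

    def __post_init__(self) -> None:
        if self.target_sd <= 0:
            raise ValueError("target_sd must be > 0")
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be > 0")


def normalize_plane(plane: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Affinely rescale ``plane`` to mean ``target_mean`` and sd ``target_sd``.

    Uses the sample (n-1) standard deviation.  Idempotent: a plane already
    at the target statistics is returned unchanged up to rounding.

    Raises
    ------
    DegenerateInputError
        If the plane is constant (sample sd is zero).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if not np.all(np.isfinite(plane)):
        raise DegenerateInputError("plane contains non-finite pixels")
    sd = plane.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant plane: standard deviation is zero")
    scaled = plane / sd * params.target_sd
    return scaled - scaled.mean() + params.target_mean


def flatten_background(plane: np.ndarray, background_sigma: float) -> np.ndarray:
    """Subtract the Gaussian-blurred local brightness tendency.

    The blur uses reflective padding at the borders.  Adding a constant to
    the input leaves the output unchanged, and a constant plane maps to
    zeros, since the blur of a constant is the constant itself.
    """
    if background_sigma <= 0:
        raise ValueError("background_sigma must be > 0")
    plane = np.asarray(plane, dtype=np.float64)
    if not np.all(np.isfinite(plane)):
        raise DegenerateInputError("plane contains non-finite pixels")
    background = ndimage.gaussian_filter(plane, sigma=background_sigma, mode="reflect")
    return plane - background


def preprocess_plane(plane: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Full preprocessing of one section plane: normalize, then flatten."""
    return flatten_background(normalize_plane(plane, params), params.background_sigma)
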