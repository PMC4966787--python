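"""Transmittance images and their conversion to optical density.

Feulgen densitometry works on transmitted light: a pixel's transmittance
``T = I / I0`` (intensity relative to the clear-background white reference)
is converted to absorbance ``OD = log10(1 / T)``, which by Beer–Lambert is
proportional to the amount of bound stain, and hence to DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

DEFAULT_SCALE = 95.04
"""Pixels per square micrometre of the reference imaging setup."""


@dataclass
class TransmittedLightImage:
    """A 2-D grayscale transmitted-light image.

    Parameters
    ----------
    pixels
        2-D array of detector intensities (brighter = more light passed).
    scale
        Pixels per square micrometre.
    i0
        True white-reference intensity, when known (synthetic images record
        it; for acquired images it is estimated from background).
    """

    pixels: np.ndarray
    scale: float = DEFAULT_SCALE
    i0: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("expected a 2-D grayscale image")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class ODImage:
    """Per-pixel optical density (absorbance) with provenance metadata."""

    od: np.ndarray
    scale: float = DEFAULT_SCALE
    white_reference: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 2:
            raise ValueError("expected a 2-D OD image")
        if np.any(self.od < 0):
            raise ValueError("optical density must be non-negative")


def _as_array(image) -> np.ndarray:
    if isinstance(image, TransmittedLightImage):
        return np.asarray(image.pixels, dtype=float)
    return np.asarray(image, dtype=float)


def estimate_white_reference(image) -> float:
    """Estimate the clear-background (white) intensity ``I0``.

    The image is split into a bright and a dark class with Otsu's threshold;
    the estimate is the median of the bright (background) class, which is
    unbiased under symmetric noise. If the two classes are not separated
    beyond the overall noise spread the whole image is treated as background
    (a blank field).

    Raises
    ------
    ValueError
        If the image is empty or contains no background signal (all dark).
    """
    arr = _as_array(image)
    if arr.size == 0:
        raise ValueError("empty image")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        if hi == 0:
            raise ValueError("no background detected (all-dark image)")
        warnings.warn("image is constant; returning its single value")
        return hi
    thresh = threshold_otsu(arr)
    upper = arr[arr > thresh]
    lower = arr[arr <= thresh]
    # Blank field: Otsu just splits the noise; class means then differ by
    # ~1.6 sigma, well under twice the overall spread.
    if upper.size == 0 or lower.size == 0 or (
        upper.mean() - lower.mean() < 2.0 * arr.std()
    ):
        estimate = float(np.median(arr))
    else:
        estimate = float(np.median(upper))
    if estimate <= 0:
        raise ValueError("no background detected")
    return estimate


def transmittance_to_od(
    image,
    white_reference: float | None = None,
    t_floor: float = 1e-3,
) -> ODImage:
    """Convert intensities to optical density, ``OD = log10(1/T)``.

    Transmittance ``T = I / white_reference`` is clamped to
    ``[t_floor, 1]`` so fully dark pixels map to a finite OD cap
    (``t_floor = 1e-3`` caps OD at 3.0) and glare maps to OD 0.
    """
    arr = _as_array(image)
    scale = image.scale if isinstance(image, TransmittedLightImage) else DEFAULT_SCALE
    if white_reference is None:
        if isinstance(image, TransmittedLightImage) and image.i0 is not None:
            white_reference = image.i0
        else:
            white_reference = estimate_white_reference(image)
    if white_reference <= 0:
        raise ValueError("white_reference must be positive")
    if not 0 < t_floor < 1:
        raise ValueError("t_floor must lie in (0, 1)")
    t = np.clip(arr / white_reference, t_floor, 1.0)
    od = -np.log10(t)
    # -0.0 from T == 1 exactly
    od[od == 0] = 0.0
    return ODImage(od=od, scale=scale, white_reference=float(white_reference))
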