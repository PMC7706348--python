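"""Global Otsu binarization of the bright-target class.

The coffee flowers are near-white against a darker green/brown canopy, so a
global histogram threshold recovers their contours precisely.  The threshold
is the intensity level maximizing the between-class variance

    sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

over the two classes induced by splitting the 256-bin grayscale histogram at
``t`` (background: intensity <= t, foreground: intensity > t).  Foreground is
the HIGH-intensity class — the targets are bright.  The weakness of any global
threshold, and the motivation for the CNN stage, is that every bright
background element (specular leaf, soil highlight) lands in the foreground
too; this module deliberately applies no morphological cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import BinaryMask, MaskProvenance, RgbImage

__all__ = ["OtsuResult", "to_grayscale", "otsu_threshold", "binarize_image"]

#: ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class OtsuResult:
    """Threshold, the between-class variance it attains, and the induced mask."""

    threshold: int
    between_class_variance: float
    mask: BinaryMask


def to_grayscale(image: RgbImage, channel: str = "luma") -> np.ndarray:
    """Project an RGB image to a uint8 intensity array.

    Default is the luma transform 0.299 R + 0.587 G + 0.114 B, rounded
    half-up.  ``channel`` may instead name a single channel ('r', 'g', 'b').
    """
    px = image.pixels.astype(np.float64)
    if channel == "luma":
        gray = px @ _LUMA
    elif channel in ("r", "g", "b"):
        gray = px[:, :, "rgb".index(channel)]
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> OtsuResult:
    """Exhaustive-histogram Otsu threshold of a uint8 intensity array.

    Evaluates every candidate split t in [0, 254] with both classes non-empty
    and returns the smallest t attaining the maximal between-class variance.
    A single-valued image is degenerate: the threshold is that value and the
    mask is all-false (no second class, variance 0).
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("cannot threshold an empty array")
    if gray.dtype != np.uint8:
        if gray.min() < 0 or gray.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        gray = gray.astype(np.uint8)

    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)

    c0 = np.cumsum(hist)                     # pixels with intensity <= t
    m0 = np.cumsum(hist * levels)            # intensity mass <= t
    w0 = c0 / n
    w1 = 1.0 - w0

    valid = (c0 > 0) & (c0 < n)
    if not valid.any():
        t = int(gray.flat[0])
        mask = BinaryMask(np.zeros(gray.shape, bool), MaskProvenance.BINARIZATION)
        return OtsuResult(threshold=t, between_class_variance=0.0, mask=mask)

    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / c0
        mu1 = (m0[-1] - m0) / (n - c0)
    var_b = np.where(valid[:255], (w0 * w1 * (mu0 - mu1) ** 2)[:255], -np.inf)

    t = int(np.argmax(var_b))  # argmax returns the SMALLEST maximizing index
    mask = BinaryMask(gray > t, MaskProvenance.BINARIZATION)
    return OtsuResult(
        threshold=t, between_class_variance=float(var_b[t]), mask=mask
    )


def binarize_image(image: RgbImage, channel: str = "luma") -> BinaryMask:
    """Grayscale projection followed by Otsu; returns the binarization mask."""
    result = otsu_threshold(to_grayscale(image, channel=channel))
    result.mask.image_id = image.id
    return result.mask
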