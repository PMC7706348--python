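"""Whole-image inference: sliding-window CNN, binarization, and Bin+CNN.

The two stages fail in complementary ways.  Global thresholding recovers
target contours precisely but also admits every bright background element;
the patch classifier knows context and rejects those, but labels a whole
31x31 neighborhood through its center pixel, so its mask is blocky at the
boundary.  Their pixel-wise AND — the Bin+CNN combination — keeps the
threshold's contours wherever the classifier agrees a flower is present,
and deletes the bright noise where it does not.

The sliding window classifies the (reflect-padded) patch centered on every
pixel of a stride grid; with stride > 1 each grid label fills its
stride x stride cell (nearest-center fill) so the CNN mask stays dense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .binarize import binarize_image
from .cnn import Network
from .io_core import BinaryMask, MaskProvenance, RgbImage

__all__ = ["PredictionBundle", "sliding_window_predict", "combine", "run_pipeline"]


@dataclass
class PredictionBundle:
    """The three masks of one pipeline run; combined = bin AND cnn, enforced."""

    bin_mask: BinaryMask
    cnn_mask: BinaryMask
    combined_mask: BinaryMask
    stride: int
    image_id: str

    def __post_init__(self) -> None:
        shapes = {
            m.values.shape
            for m in (self.bin_mask, self.cnn_mask, self.combined_mask)
        }
        if len(shapes) != 1:
            raise ValueError(f"bundle masks disagree in shape: {shapes}")
        if not np.array_equal(
            self.combined_mask.values, self.bin_mask.values & self.cnn_mask.values
        ):
            raise ValueError("combined mask must equal bin AND cnn pixel-wise")


def sliding_window_predict(
    network: Network,
    image: RgbImage,
    stride: int = 1,
    batch_size: int = 512,
    classify=None,
) -> BinaryMask:
    """Dense CNN mask from stride-grid patch classification.

    ``classify`` may replace the network's batch classifier (signature
    ``blocks (N,S,S,3) uint8 -> bool (N,)``) — used for testing the window
    mechanics independently of training.  Batching never changes results.
    """
    h, w = image.height, image.width
    if stride < 1 or stride > min(h, w):
        raise ValueError(f"stride must be in [1, {min(h, w)}], got {stride}")
    size = network.cfg.input_size if network is not None else 31
    if size % 2 == 0:
        raise ValueError("network input_size must be odd")
    r = size // 2
    if classify is None:
        classify = lambda blocks: network.predict_proba(blocks)[:, 1] > 0.5

    padded = np.pad(image.pixels, ((r, r), (r, r), (0, 0)), mode="reflect")
    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    # all windows as a strided view; subsample the stride grid
    win = sliding_window_view(padded, (size, size), axis=(0, 1))
    grid = win[np.ix_(rows, cols)]  # (nr, nc, 3, S, S)
    nr, nc = len(rows), len(cols)
    blocks = grid.reshape(nr * nc, 3, size, size).transpose(0, 2, 3, 1)

    labels = np.empty(nr * nc, dtype=bool)
    for start in range(0, len(labels), batch_size):
        chunk = np.ascontiguousarray(blocks[start : start + batch_size])
        labels[start : start + batch_size] = classify(chunk)
    grid_labels = labels.reshape(nr, nc)

    # nearest-center fill: each pixel takes the label of its closest grid point
    ridx = np.clip(np.round(np.arange(h) / stride).astype(int), 0, nr - 1)
    cidx = np.clip(np.round(np.arange(w) / stride).astype(int), 0, nc - 1)
    dense = grid_labels[np.ix_(ridx, cidx)]
    return BinaryMask(dense, MaskProvenance.CNN, image_id=image.id)


def combine(bin_mask: BinaryMask, cnn_mask: BinaryMask) -> BinaryMask:
    """Pixel-wise AND of the binarization and CNN masks."""
    if bin_mask.values.shape != cnn_mask.values.shape:
        raise ValueError(
            f"shape mismatch: {bin_mask.values.shape} vs {cnn_mask.values.shape}"
        )
    return BinaryMask(
        bin_mask.values & cnn_mask.values,
        MaskProvenance.COMBINED,
        image_id=bin_mask.image_id,
    )


def run_pipeline(
    network: Network, image: RgbImage, stride: int = 1, classify=None
) -> PredictionBundle:
    """Full Bin+CNN inference on one image; deterministic given its inputs."""
    image.require_min_size()
    bin_mask = binarize_image(image)
    cnn_mask = sliding_window_predict(network, image, stride=stride, classify=classify)
    return PredictionBundle(
        bin_mask=bin_mask,
        cnn_mask=cnn_mask,
        combined_mask=combine(bin_mask, cnn_mask),
        stride=stride,
        image_id=image.id,
    )
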