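"""Superpixel oversegmentation, region merging, and superpixel-level truth.

Ground truth and positive training samples are anchored on regions rather
than raw pixels: an image is oversegmented into SLICO superpixels (the
parameter-free SLIC variant with per-cluster adaptive compactness), adjacent
superpixels are agglomerated into a target number of merged regions, and the
region centroids seed the 31x31 positive patches.  Ground-truth masks are
built at superpixel granularity: every superpixel containing a marked flower
pixel becomes foreground in full.

Oversegmentation delegates to :func:`skimage.segmentation.slic` (SLICO mode);
a post-pass guarantees the partition contract this package relies on —
labels 0..n-1 with no gaps, each segment 4-connected.  Merging is a greedy
agglomeration on the region adjacency graph: repeatedly fuse the adjacent
pair whose mean Lab colors are closest until exactly the requested number of
regions remains (ties broken by the smaller label pair).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab
from skimage.segmentation import slic as _skimage_slic

from .io_core import BinaryMask, MaskProvenance, PixelCoord, RgbImage

__all__ = [
    "SuperpixelMap",
    "MergedRegionSet",
    "slic_segment",
    "merge_regions",
    "build_ground_truth",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


@dataclass
class SuperpixelMap:
    """Gap-free partition of an image into 4-connected segments."""

    labels: np.ndarray
    image_id: str = "image"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int64)

    @property
    def n_segments(self) -> int:
        return int(self.labels.max()) + 1

    def segment_areas(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_segments)


@dataclass
class MergedRegionSet:
    """Unions of whole superpixels with their (pixel-snapped) centroids."""

    region_labels: np.ndarray
    centers: list[PixelCoord]

    @property
    def n_regions(self) -> int:
        return len(self.centers)


def _relabel_connected(labels: np.ndarray) -> np.ndarray:
    """Split 4-disconnected segments, then absorb orphan components.

    Each connected component keeps its own label; every component that is not
    the largest component of its original segment is relabeled to its largest
    4-adjacent neighbor component.  The result is compact (0..n-1) and every
    segment is 4-connected.
    """
    # decompose into 4-connected components, globally labeled
    comp = np.zeros_like(labels)
    n_comp = 0
    for lab in np.unique(labels):
        cc, k = ndimage.label(labels == lab, structure=_FOUR_CONN)
        comp[cc > 0] = cc[cc > 0] + n_comp
        n_comp += k
    comp -= 1  # 0-based

    areas = np.bincount(comp.ravel(), minlength=n_comp)
    # largest component per original segment survives
    owner = np.zeros(n_comp, dtype=np.int64)
    for lab in np.unique(labels):
        members = np.unique(comp[labels == lab])
        owner[members] = members[np.argmax(areas[members])]

    keep = np.flatnonzero(owner == np.arange(n_comp))
    orphans = [c for c in range(n_comp) if owner[c] != c]
    if orphans:
        # adjacency of components along 4-neighbor pixel pairs
        pairs = set()
        for a, b in ((comp[:-1, :], comp[1:, :]), (comp[:, :-1], comp[:, 1:])):
            diff = a != b
            pairs.update(zip(a[diff].tolist(), b[diff].tolist()))
        adj: dict[int, set[int]] = {c: set() for c in range(n_comp)}
        for a, b in pairs:
            adj[a].add(b)
            adj[b].add(a)
        # absorb orphans smallest-first so chains resolve to kept components
        for c in sorted(orphans, key=lambda c: (areas[c], c)):
            neighbors = [n for n in adj[c] if owner[n] == n]
            if not neighbors:
                neighbors = list(adj[c])
            if not neighbors:  # single-segment image; keep as is
                owner[c] = c
                continue
            target = owner[max(neighbors, key=lambda n: (areas[n], -n))]
            owner[c] = target
            for n in adj[c]:
                adj[n].discard(c)
                adj[n].add(target)
                adj[target].add(n)
            adj[target].discard(target)

    final = owner[comp]
    # compact labels to 0..n-1
    _, compacted = np.unique(final, return_inverse=True)
    return compacted.reshape(labels.shape)


def slic_segment(
    image: RgbImage,
    n_target: int,
    compactness_mode: str | float = "slico_adaptive",
) -> SuperpixelMap:
    """SLICO-style oversegmentation into approximately ``n_target`` segments.

    ``compactness_mode`` is ``"slico_adaptive"`` (per-cluster adaptive
    compactness, the default) or a fixed numeric compactness m.
    """
    h, w = image.height, image.width
    if not (1 <= n_target <= h * w):
        raise ValueError(
            f"n_target must be in [1, {h * w}] for a {h}x{w} image, got {n_target}"
        )
    if n_target == 1:
        return SuperpixelMap(np.zeros((h, w), np.int64), image.id)
    slico = compactness_mode == "slico_adaptive"
    labels = _skimage_slic(
        image.pixels,
        n_segments=n_target,
        compactness=10.0 if slico else float(compactness_mode),
        slic_zero=slico,
        max_num_iter=10,
        start_label=0,
        enforce_connectivity=True,
        channel_axis=2,
    )
    return SuperpixelMap(_relabel_connected(labels), image.id)


def _region_adjacency(labels: np.ndarray) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for a, b in ((labels[:-1, :], labels[1:, :]), (labels[:, :-1], labels[:, 1:])):
        diff = a != b
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def _snap_centroid(labels: np.ndarray, region: int) -> PixelCoord:
    rows, cols = np.nonzero(labels == region)
    r, c = rows.mean(), cols.mean()
    ri, ci = int(round(r)), int(round(c))
    if labels[min(ri, labels.shape[0] - 1), min(ci, labels.shape[1] - 1)] == region:
        return PixelCoord(ri, ci)
    # centroid fell outside a non-convex region: snap to the nearest member pixel
    d2 = (rows - r) ** 2 + (cols - c) ** 2
    k = int(np.argmin(d2))
    return PixelCoord(int(rows[k]), int(cols[k]))


def merge_regions(
    spx: SuperpixelMap, image: RgbImage, n_regions_target: int
) -> MergedRegionSet:
    """Greedy agglomeration of adjacent superpixels by mean-Lab similarity.

    Repeatedly merges the adjacent pair with the smallest Euclidean distance
    between area-weighted mean Lab colors until exactly ``n_regions_target``
    regions remain.  Ties break on the smaller ``(label_i, label_j)`` pair.
    """
    n = spx.n_segments
    if not (1 <= n_regions_target <= n):
        raise ValueError(
            f"n_regions_target must be in [1, {n}], got {n_regions_target}"
        )
    labels = spx.labels
    lab = rgb2lab(image.pixels)
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n).astype(np.float64)
    color_sum = np.stack(
        [np.bincount(flat, weights=lab[:, :, c].ravel(), minlength=n) for c in range(3)],
        axis=1,
    )

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in _region_adjacency(labels):
        adj[a].add(b)
        adj[b].add(a)

    def dist(a: int, b: int) -> float:
        ca = color_sum[a] / area[a]
        cb = color_sum[b] / area[b]
        return float(np.sqrt(((ca - cb) ** 2).sum()))

    # heap entries carry per-region version stamps; a merge bumps the merged
    # region's version so entries with outdated mean colors are skipped
    version = [0] * n
    heap = [(dist(a, b), a, b, 0, 0) for a, b in _region_adjacency(labels)]
    heapq.heapify(heap)

    n_live = n
    while n_live > n_regions_target:
        if not heap:
            raise RuntimeError(
                f"adjacency exhausted at {n_live} regions; "
                f"cannot reach {n_regions_target}"
            )
        d, a, b, va, vb = heapq.heappop(heap)
        if find(a) != a or find(b) != b or version[a] != va or version[b] != vb:
            continue  # stale entry
        # merge b into a (a < b by construction of the pair set)
        parent[b] = a
        version[a] += 1
        area[a] += area[b]
        color_sum[a] += color_sum[b]
        adj[a].discard(b)
        for nb in adj[b]:
            nb_root = find(nb)
            if nb_root != a:
                adj[a].add(nb_root)
                adj[nb_root].discard(b)
                adj[nb_root].add(a)
        del adj[b]
        for nb in sorted(adj[a]):
            lo, hi = min(a, nb), max(a, nb)
            heapq.heappush(heap, (dist(lo, hi), lo, hi, version[lo], version[hi]))
        n_live -= 1

    roots = np.array([find(i) for i in range(n)])
    _, compact = np.unique(roots, return_inverse=True)
    region_labels = compact[labels]
    centers = [
        _snap_centroid(region_labels, r) for r in range(n_regions_target)
    ]
    return MergedRegionSet(region_labels=region_labels, centers=centers)


def build_ground_truth(
    spx: SuperpixelMap, flower_marks: list[PixelCoord]
) -> BinaryMask:
    """Mask that is true on every superpixel containing at least one mark.

    This is how reference annotation is quantized: a click anywhere inside a
    flower lights up the whole superpixel.  An empty mark list yields an
    all-false mask.
    """
    h, w = spx.labels.shape
    marked = np.zeros(spx.n_segments, bool)
    for m in flower_marks:
        m.validate(h, w)
        marked[spx.labels[m.row, m.col]] = True
    return BinaryMask(
        marked[spx.labels], MaskProvenance.GROUND_TRUTH, image_id=spx.image_id
    )
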