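"""Construction of the patch training set for the classifier.

Positive samples are 31x31x3 neighborhood blocks centered on the recorded
centers of flower regions (merged-superpixel centroids in real imagery,
planted flower centers in synthetic scenes), taken only from images that
contain flowers.  Negative samples are blocks at centers drawn uniformly
without replacement from images verified to be flower-free.  Blocks whose
window crosses the image border are completed by reflect padding (the edge
row/column is mirrored, not repeated), preserving local intensity statistics.

A :class:`PatchManifest` carries the samples plus the metadata needed for
exact reproduction (patch size and the sampling seed); written to disk it
becomes a CSV of ``path,label,image_id,row,col`` with blocks stored as PNG
files in label-named subdirectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .io_core import PixelCoord, RgbImage

__all__ = [
    "PatchSample",
    "PatchManifest",
    "extract_patch",
    "build_positive_set",
    "build_negative_set",
    "write_manifest",
    "read_manifest",
]


@dataclass
class PatchSample:
    block: np.ndarray
    label: str  # 'positive' | 'negative'
    image_id: str
    center: PixelCoord
    path: Path | None = None

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be 'positive' or 'negative', got {self.label!r}")
        self.block = np.asarray(self.block, dtype=np.uint8)


@dataclass
class PatchManifest:
    samples: list[PatchSample]
    patch_size: int = 31
    seed: int = 0

    @property
    def n_positive(self) -> int:
        return sum(1 for s in self.samples if s.label == "positive")

    @property
    def n_negative(self) -> int:
        return sum(1 for s in self.samples if s.label == "negative")


def extract_patch(image: RgbImage, center: PixelCoord, patch_size: int = 31) -> np.ndarray:
    """Square window of ``patch_size``² pixels centered at ``center``.

    ``patch_size`` must be odd.  Windows crossing the border are completed by
    reflect-padding the image.
    """
    if patch_size % 2 == 0:
        raise ValueError(f"patch_size must be odd, got {patch_size}")
    center.validate(image.height, image.width)
    r = patch_size // 2
    padded = np.pad(image.pixels, ((r, r), (r, r), (0, 0)), mode="reflect")
    return padded[
        center.row : center.row + patch_size, center.col : center.col + patch_size
    ].copy()


def build_positive_set(
    flower_images: list[RgbImage],
    centers_per_image: list[list[PixelCoord]],
    patch_size: int = 31,
) -> list[PatchSample]:
    """One positive sample per recorded flower-region center.

    Duplicate centers yield duplicate samples; deduplication (by exact
    coordinate) is the caller's responsibility, done upstream of this step.
    """
    if len(flower_images) != len(centers_per_image):
        raise ValueError("flower_images and centers_per_image must align")
    samples = [
        PatchSample(
            block=extract_patch(img, c, patch_size),
            label="positive",
            image_id=img.id,
            center=c,
        )
        for img, centers in zip(flower_images, centers_per_image)
        for c in centers
    ]
    if not samples:
        raise ValueError("no positive centers given; cannot build a training set")
    return samples


def build_negative_set(
    background_images: list[RgbImage],
    n_per_image: int,
    patch_size: int = 31,
    seed: int = 0,
) -> list[PatchSample]:
    """``n_per_image`` blocks per flower-free image at seeded random centers.

    Centers are drawn uniformly without replacement from all pixel positions
    of each image; the draw is fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    samples: list[PatchSample] = []
    for img in background_images:
        n_pix = img.height * img.width
        if n_per_image > n_pix:
            raise ValueError(
                f"n_per_image={n_per_image} exceeds pixel count {n_pix} of {img.id!r}"
            )
        flat = rng.choice(n_pix, size=n_per_image, replace=False)
        for f in flat:
            c = PixelCoord(int(f // img.width), int(f % img.width))
            samples.append(
                PatchSample(
                    block=extract_patch(img, c, patch_size),
                    label="negative",
                    image_id=img.id,
                    center=c,
                )
            )
    return samples


def write_manifest(manifest: PatchManifest, out_dir: str | Path) -> Path:
    """Write blocks as PNGs in label subdirectories plus a CSV manifest."""
    out_dir = Path(out_dir)
    rows = []
    counters: dict[str, int] = {"positive": 0, "negative": 0}
    for s in manifest.samples:
        sub = out_dir / s.label
        sub.mkdir(parents=True, exist_ok=True)
        name = f"{s.image_id}_{s.center.row}_{s.center.col}_{counters[s.label]:05d}.png"
        counters[s.label] += 1
        s.path = sub / name
        Image.fromarray(s.block, mode="RGB").save(s.path, format="PNG")
        rows.append(
            {
                "path": str(s.path.relative_to(out_dir)),
                "label": s.label,
                "image_id": s.image_id,
                "row": s.center.row,
                "col": s.center.col,
            }
        )
    csv_path = out_dir / "manifest.csv"
    meta = pd.DataFrame(rows, columns=["path", "label", "image_id", "row", "col"])
    meta.to_csv(csv_path, index=False)
    (out_dir / "manifest_meta.csv").write_text(
        "patch_size,seed,n_positive,n_negative\n"
        f"{manifest.patch_size},{manifest.seed},"
        f"{manifest.n_positive},{manifest.n_negative}\n"
    )
    return csv_path


def read_manifest(csv_path: str | Path) -> PatchManifest:
    csv_path = Path(csv_path)
    base = csv_path.parent
    df = pd.read_csv(csv_path)
    samples = []
    patch_size = 31
    meta = base / "manifest_meta.csv"
    seed = 0
    if meta.exists():
        m = pd.read_csv(meta)
        patch_size = int(m["patch_size"].iloc[0])
        seed = int(m["seed"].iloc[0])
    for _, row in df.iterrows():
        p = base / row["path"]
        with Image.open(p) as im:
            block = np.asarray(im.convert("RGB"))
        samples.append(
            PatchSample(
                block=block,
                label=row["label"],
                image_id=row["image_id"],
                center=PixelCoord(int(row["row"]), int(row["col"])),
                path=p,
            )
        )
    return PatchManifest(samples=samples, patch_size=patch_size, seed=seed)
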