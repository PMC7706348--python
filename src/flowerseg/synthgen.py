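"""Seeded generator of synthetic canopy scenes with pixel-exact ground truth.

Scenes emulate the imaging regime of ground-based time-lapse flower
monitoring: near-white elliptical flower clusters of roughly 900 px² sitting
on a darker, low-frequency textured, green-dominant canopy, plus small
bright distractors (specular leaves, soil highlights) whose *pixel values*
overlap the flowers' but whose spatial context does not — they exist to be
captured by the global threshold and rejected by the patch classifier.

Two illumination regimes are modeled: ``soft`` (the default rendering) and
``intense``, which multiplies all channels by a gain and clips, brightening
the background toward the flower range and stressing the binarization stage.

All randomness flows from the scene seed through named substreams
(background, placement, colors, distractors), so extending one stream never
perturbs the others and every scene is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import BinaryMask, MaskProvenance, PixelCoord, RgbImage, write_image, write_mask
from .trainset import PatchManifest, build_negative_set, build_positive_set

__all__ = ["SceneSpec", "SyntheticScene", "generate_scene", "generate_benchmark", "scene_to_trainset"]

_STREAMS = {
    "background": 0,
    "placement": 1,
    "colors": 2,
    "distractors": 3,
    "annotation": 4,
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; fully determines it given ``seed``."""

    height: int = 256
    width: int = 256
    n_flowers: int = 5
    flower_area_mean: float = 900.0  # px², matches the ~900 px target size
    flower_area_cv: float = 0.45  # apparent sizes vary with distance/angle
    flower_luma_range: tuple[float, float] = (225.0, 255.0)
    background_luma_range: tuple[float, float] = (40.0, 140.0)
    background_texture_scale: int = 16  # px, correlation length of the canopy
    n_distractors: int = 40
    distractor_area_range: tuple[float, float] = (4.0, 40.0)
    illumination: str = "soft"  # 'soft' | 'intense'
    intense_gain: float = 1.7
    perspective_squash: float = 0.75  # vertical/horizontal ellipse-axis ratio
    center_jitter: float = 0.7  # recorded centers land within this fraction of
    #   the flower radius — region centroids are not exact bloom centers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.illumination not in ("soft", "intense"):
            raise ValueError(f"illumination must be 'soft' or 'intense', got {self.illumination!r}")
        if self.distractor_area_range[1] > 50:
            raise ValueError("distractor areas must stay below 50 px² (patch context must distinguish them)")
        total = self.n_flowers * self.flower_area_mean
        if total >= 0.3 * self.height * self.width:
            raise ValueError(
                f"infeasible spec: total flower area {total:.0f} px² exceeds 30% of "
                f"the {self.height}x{self.width} image"
            )


@dataclass
class SyntheticScene:
    image: RgbImage
    truth: BinaryMask
    flower_centers: list[PixelCoord]
    spec: SceneSpec


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency green-dominant canopy texture as float64 H×W×3."""
    h, w = spec.height, spec.width
    noise = rng.normal(size=(h, w))
    smooth = ndimage.gaussian_filter(noise, sigma=spec.background_texture_scale / 2.0)
    z = (smooth - smooth.mean()) / max(smooth.std(), 1e-9)
    lo, hi = spec.background_luma_range
    center, spread = (lo + hi) / 2.0, (hi - lo) / 6.0
    luma = np.clip(center + spread * z, lo, hi)
    # green-dominant hue around the luma level
    return np.clip(
        np.stack([luma * 0.95, luma * 1.10, luma * 0.70], axis=2), 0, 255
    )


def _place_centers(
    spec: SceneSpec, radii: np.ndarray, rng: np.random.Generator, max_tries: int = 2000
) -> list[tuple[int, int]]:
    """Non-overlapping flower centers by rejection sampling (capped retries)."""
    h, w = spec.height, spec.width
    centers: list[tuple[int, int]] = []
    for i, r in enumerate(radii):
        margin = int(np.ceil(r)) + 3
        if 2 * margin >= min(h, w):
            raise ValueError(f"flower radius {r:.1f} px does not fit in the scene")
        for _ in range(max_tries):
            cr = int(rng.integers(margin, h - margin))
            cc = int(rng.integers(margin, w - margin))
            if all(
                np.hypot(cr - pr, cc - pc) > r + radii[j] + 4
                for j, (pr, pc) in enumerate(centers)
            ):
                centers.append((cr, cc))
                break
        else:
            raise ValueError(
                f"could not place flower {i} without overlap after {max_tries} tries"
            )
    return centers


def _ellipse_alpha(
    h: int, w: int, center: tuple[int, int], a: float, b: float, soft: float = 2.0
) -> np.ndarray:
    """Anti-aliased ellipse coverage: 1 inside, 0 outside, ±``soft`` px edge."""
    rr, cc = np.mgrid[0:h, 0:w]
    rho = np.sqrt(((cc - center[1]) / a) ** 2 + ((rr - center[0]) / b) ** 2)
    t = (1.0 - rho) * min(a, b)  # approx signed distance (px) to the boundary
    return np.clip((t + soft) / (2.0 * soft), 0.0, 1.0)


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene with its ground truth, fully determined by the seed."""
    h, w = spec.height, spec.width
    bg_rng = _stream(spec.seed, "background")
    place_rng = _stream(spec.seed, "placement")
    color_rng = _stream(spec.seed, "colors")
    distract_rng = _stream(spec.seed, "distractors")

    img = _background(spec, bg_rng)
    truth = np.zeros((h, w), bool)
    centers: list[PixelCoord] = []

    if spec.n_flowers > 0:
        # lognormal areas: flower clusters appear at unequal sizes (distance,
        # viewing angle); clipped so the window still covers the average one
        cv = spec.flower_area_cv
        sigma2 = np.log1p(cv * cv)
        mu = np.log(spec.flower_area_mean) - sigma2 / 2.0
        lo_a = min(300.0, spec.flower_area_mean / 3.0)
        hi_a = 2.2 * spec.flower_area_mean
        # resample the area vector until the truth-budget band (±30% of
        # n_flowers × mean area) is attainable by the clipped draws
        for _ in range(100):
            areas = np.clip(
                place_rng.lognormal(mu, np.sqrt(sigma2), spec.n_flowers), lo_a, hi_a
            )
            if abs(areas.sum() - spec.n_flowers * spec.flower_area_mean) <= (
                0.25 * spec.n_flowers * spec.flower_area_mean
            ):
                break
        semi_a = np.sqrt(areas / (np.pi * spec.perspective_squash))
        semi_b = semi_a * spec.perspective_squash
        placed = _place_centers(spec, semi_a, place_rng)
        annot_rng = _stream(spec.seed, "annotation")
        for (cr, cc), a, b in zip(placed, semi_a, semi_b):
            alpha = _ellipse_alpha(h, w, (cr, cc), a, b)
            luma = color_rng.uniform(*spec.flower_luma_range)
            color = np.clip(np.array([luma, luma, 0.97 * luma]), 0, 255)
            img = alpha[:, :, None] * color + (1 - alpha[:, :, None]) * img
            truth |= alpha >= 0.5
            # recorded center: a point in the flower's interior, not the exact
            # geometric centroid (emulates merged-region centroid noise)
            theta = annot_rng.uniform(0.0, 2 * np.pi)
            rho = spec.center_jitter * np.sqrt(annot_rng.uniform())
            jr = int(round(cr + rho * b * np.sin(theta)))
            jc = int(round(cc + rho * a * np.cos(theta)))
            if not (0 <= jr < h and 0 <= jc < w) or not truth[jr, jc]:
                jr, jc = cr, cc
            centers.append(PixelCoord(jr, jc))

    if spec.n_distractors > 0:
        flower_info = (
            [(c.row, c.col, float(a)) for c, a in zip(centers, semi_a)]
            if spec.n_flowers > 0
            else []
        )
        for _ in range(spec.n_distractors):
            area = distract_rng.uniform(*spec.distractor_area_range)
            r = float(np.sqrt(area / np.pi))
            for _try in range(200):
                dr = int(distract_rng.integers(2, h - 2))
                dc = int(distract_rng.integers(2, w - 2))
                if all(
                    np.hypot(dr - fr, dc - fc) > fa + r + 5
                    for fr, fc, fa in flower_info
                ):
                    break
            else:
                continue  # no room; skip this distractor
            alpha = _ellipse_alpha(h, w, (dr, dc), r, r, soft=1.0)
            luma = distract_rng.uniform(*spec.flower_luma_range)
            color = np.clip(np.array([luma, luma, 0.97 * luma]), 0, 255)
            img = alpha[:, :, None] * color + (1 - alpha[:, :, None]) * img

    if spec.illumination == "intense":
        img = np.clip(img * spec.intense_gain, 0, 255)

    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    scene_id = f"scene_{spec.seed:05d}_{spec.illumination}"
    return SyntheticScene(
        image=RgbImage(pixels=pixels, id=scene_id),
        truth=BinaryMask(truth, MaskProvenance.GROUND_TRUTH, image_id=scene_id),
        flower_centers=centers,
        spec=spec,
    )


def generate_benchmark(
    spec: SceneSpec,
    n_scenes: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """``n_scenes`` scenes with seeds ``seed .. seed + n_scenes - 1``.

    If ``out_dir`` is given, writes ``scene_XXX.png``, ``truth_XXX.png`` and
    ``manifest.csv`` there.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    scenes = [generate_scene(replace(spec, seed=seed + i)) for i in range(n_scenes)]
    rows = []
    for i, sc in enumerate(scenes):
        row = {
            "index": i,
            "seed": sc.spec.seed,
            "illumination": sc.spec.illumination,
            "n_flowers": len(sc.flower_centers),
            "truth_pixels": sc.truth.true_count,
        }
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            row["image"] = f"scene_{i:03d}.png"
            row["truth"] = f"truth_{i:03d}.png"
            write_image(sc.image, out / row["image"])
            write_mask(sc.truth, out / row["truth"])
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return scenes, manifest


def scene_to_trainset(
    scenes: list[SyntheticScene],
    background_scenes: list[SyntheticScene],
    n_neg_per_image: int,
    seed: int,
    patch_size: int = 31,
) -> PatchManifest:
    """Patch manifest from synthetic scenes: positives at planted flower
    centers, negatives sampled from flower-free scenes."""
    for bs in background_scenes:
        if bs.spec.n_flowers != 0:
            raise ValueError(
                f"background scene {bs.image.id!r} has n_flowers="
                f"{bs.spec.n_flowers}; negatives require flower-free scenes"
            )
    positives = build_positive_set(
        [s.image for s in scenes],
        [s.flower_centers for s in scenes],
        patch_size=patch_size,
    )
    negatives = build_negative_set(
        [s.image for s in background_scenes],
        n_per_image=n_neg_per_image,
        patch_size=patch_size,
        seed=seed,
    )
    return PatchManifest(samples=positives + negatives, patch_size=patch_size, seed=seed)
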