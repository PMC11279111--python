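"""Synthetic fluorescence-like scenes and saturation artifacts.

Real fluorescence micrographs of stained cells show textured, roughly
elliptical bright bodies over a dark, slightly noisy background; sensor
clipping produces contiguous clusters of pixels pinned at the maximum gray
level.  This module emulates exactly those ingredients so the screening,
training and evaluation code can be exercised without downloading any
high-throughput-screening dataset.

All randomness flows through one ``numpy`` generator seeded per call:
identical specs reproduce bit-identical images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .screening import GrayImage

#: normalized intensity that maps to the raw saturation level (255 in 8-bit)
SATURATION_VALUE = 1.0


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one synthetic scene.

    ``texture_scale`` is the correlation length (pixels) of the
    multiplicative intra-cell texture; ``texture_amplitude`` its relative
    strength.  ``noise_amplitude`` is additive background sensor noise
    (std, normalized units), required so clean scenes have the gray-level
    diversity (entropy) of real micrographs.
    """

    image_size: int = 128
    n_cells: int = 12
    cell_radius_range: tuple[float, float] = (8.0, 18.0)
    texture_scale: float = 3.0
    texture_amplitude: float = 0.35
    background_level: float = 0.10
    noise_amplitude: float = 0.02
    artifact_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (0.0 <= self.artifact_fraction < 1.0):
            raise ValueError("artifact_fraction must be in [0, 1)")
        rmin, rmax = self.cell_radius_range
        if rmin <= 0 or rmin > rmax:
            raise ValueError("cell radii must be positive with min <= max")


def generate_clean_image(spec: SyntheticSceneSpec) -> GrayImage:
    """Render textured elliptical cell bodies over a noisy dark background.

    The result is strictly inside [0, 1): no pixel reaches the saturation
    value, so clean scenes always pass the no-saturated-pixel screen.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    img = np.full((s, s), spec.background_level, dtype=np.float32)

    for _ in range(spec.n_cells):
        cx, cy = rng.uniform(0, s, size=2)
        a = rng.uniform(*spec.cell_radius_range)
        b = rng.uniform(*spec.cell_radius_range)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.35, 0.75)
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        r2 = (u / a) ** 2 + (v / b) ** 2
        body = np.exp(-2.5 * r2).astype(np.float32)  # smooth radial falloff
        if spec.texture_amplitude > 0:
            noise = rng.uniform(-1.0, 1.0, size=(s, s)).astype(np.float32)
            texture = 1.0 + spec.texture_amplitude * gaussian_filter(
                noise, spec.texture_scale) * 3.0
        else:
            texture = 1.0
        img += amp * body * texture

    if spec.noise_amplitude > 0:
        img += rng.normal(0.0, spec.noise_amplitude, size=(s, s)).astype(np.float32)

    img = np.clip(img, 0.0, 0.98)
    return GrayImage(img.astype(np.float32))


def inject_saturation_artifact(image: GrayImage, fraction: float,
                               seed: int, n_blobs: int | None = None
                               ) -> tuple[GrayImage, np.ndarray]:
    """Clip one or more contiguous blobs to the saturation value.

    Blobs are grown from random seed points by compactness-weighted frontier
    accretion (clusters, not scatter), until the union covers
    ``round(fraction * n_pixels)`` pixels exactly.  Returns the clipped
    image and the binary mask of exactly the clipped pixels.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    h, w = image.data.shape
    target = max(1, int(round(fraction * h * w)))
    if n_blobs is None:
        n_blobs = int(rng.integers(1, 4)) if target >= 48 else 1
    mask = _grow_blobs((h, w), target, n_blobs, rng)
    out = image.data.copy()
    out[mask] = SATURATION_VALUE
    return GrayImage(out, bit_depth=image.bit_depth), mask.astype(np.uint8)


def _grow_blobs(shape: tuple[int, int], target: int, n_blobs: int,
                rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    seeds = [(int(rng.integers(h)), int(rng.integers(w)))
             for _ in range(n_blobs)]
    frontiers: list[dict] = []
    grown = 0
    for (y, x) in seeds:
        if not mask[y, x]:
            mask[y, x] = True
            grown += 1
        frontiers.append({})
        _push_neighbors(mask, y, x, frontiers[-1])
    bi = 0
    while grown < target:
        fr = frontiers[bi % n_blobs]
        bi += 1
        if not fr:
            continue
        keys = list(fr.keys())
        # weight by filled-neighbor count cubed -> compact, disk-like blobs
        wts = np.array([fr[k] ** 3 for k in keys], dtype=np.float64)
        pick = keys[rng.choice(len(keys), p=wts / wts.sum())]
        del fr[pick]
        y, x = pick
        if mask[y, x]:
            continue
        mask[y, x] = True
        grown += 1
        _push_neighbors(mask, y, x, fr)
    return mask


def _push_neighbors(mask: np.ndarray, y: int, x: int, frontier: dict) -> None:
    h, w = mask.shape
    for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
        if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx]:
            filled = sum(mask[qy, qx]
                         for qy, qx in ((ny - 1, nx), (ny + 1, nx),
                                        (ny, nx - 1), (ny, nx + 1))
                         if 0 <= qy < h and 0 <= qx < w)
            frontier[(ny, nx)] = max(filled, 1)


def write_fixture_set(out_dir: str | Path, n_images: int,
                      spec: SyntheticSceneSpec,
                      bit_depth: int = 8) -> Path:
    """Write a PNG (8-bit) or TIFF (16-bit) fixture set plus a manifest CSV
    (filename, seed, artifact_fraction, mask filename)."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "seed", "artifact_fraction", "mask_filename"])
        for i in range(n_images):
            sp = replace(spec, seed=spec.seed + i)
            img = generate_clean_image(sp)
            mask_name = ""
            if sp.artifact_fraction > 0:
                img, mask = inject_saturation_artifact(
                    img, sp.artifact_fraction, seed=sp.seed + 10_000)
                mask_name = f"mask_{i:04d}.png"
                iio.imwrite(out_dir / mask_name, (mask * 255).astype(np.uint8))
            if bit_depth == 8:
                name = f"image_{i:04d}.png"
                iio.imwrite(out_dir / name, img.to_raw(8))
            else:
                name = f"image_{i:04d}.tiff"
                tifffile.imwrite(out_dir / name, img.to_raw(16))
            writer.writerow([name, sp.seed, sp.artifact_fraction, mask_name])
    return manifest


def make_scene_batch(n: int, spec: SyntheticSceneSpec) -> list[GrayImage]:
    """n clean scenes with consecutive seeds starting at ``spec.seed``."""
    return [generate_clean_image(replace(spec, seed=spec.seed + i))
            for i in range(n)]
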