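"""Masks, Canny edge maps, and the edge-network input planes.

Conventions used everywhere in the package:

* masks are binary 2-D arrays with **1 = region to restore**;
* the masked grayscale plane is filled with the saturation value 1.0 inside
  the mask, because at inference the real artifact region *is* saturated
  white — train and test inputs then look alike;
* edge maps are binary {0, 1} arrays of the same shape as their image.
"""

from __future__ import annotations

import numpy as np
from skimage import feature

from .screening import GrayImage
from .synthetic import _grow_blobs


def canny_edges(image: GrayImage, sigma: float = 2.0,
                low: float = 0.85, high: float = 0.95) -> np.ndarray:
    """Canny edge map (Gaussian smoothing, non-max suppression, hysteresis).

    ``low``/``high`` are per-image gradient-magnitude quantiles in (0, 1],
    so the detector adapts to each image's contrast.  A constant image
    yields an empty edge map.
    """
    if not (0.0 < low < high <= 1.0):
        raise ValueError("need 0 < low < high <= 1")
    if np.ptp(image.data) == 0:
        return np.zeros(image.shape, dtype=np.uint8)
    edges = feature.canny(image.data.astype(np.float64), sigma=sigma,
                          low_threshold=low, high_threshold=high,
                          use_quantiles=True)
    return edges.astype(np.uint8)


def random_mask(shape: tuple[int, int], area_fraction: float,
                style: str = "blobs", seed: int = 0,
                n_regions: int = 1) -> np.ndarray:
    """Random restoration mask covering ``area_fraction`` of the image.

    ``blobs`` grows contiguous irregular regions (the shape of real
    saturation artifacts); ``rectangles`` places axis-aligned blocks.  The
    covered area is exact for blobs and within +-2% for rectangles.
    """
    if not (0.0 < area_fraction < 1.0):
        raise ValueError("area_fraction must be in (0, 1)")
    h, w = shape
    rng = np.random.default_rng(seed)
    target = max(1, int(round(area_fraction * h * w)))
    if style == "blobs":
        return _grow_blobs(shape, target, n_regions, rng).astype(np.uint8)
    if style == "rectangles":
        mask = np.zeros(shape, dtype=np.uint8)
        side_h = int(round(np.sqrt(target * h / w)))
        side_w = int(round(target / max(side_h, 1)))
        side_h, side_w = min(side_h, h), min(side_w, w)
        for _ in range(n_regions):
            y0 = int(rng.integers(0, h - side_h + 1))
            x0 = int(rng.integers(0, w - side_w + 1))
            mask[y0:y0 + side_h, x0:x0 + side_w] = 1
        return mask
    raise ValueError(f"unknown mask style {style!r}")


def make_edge_gan_input(image: GrayImage, mask: np.ndarray,
                        sigma: float = 2.0, low: float = 0.85,
                        high: float = 0.95
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three aligned planes fed to the edge network.

    Returns ``(masked grayscale, mask, masked edge map)`` where the masked
    grayscale is ``image*(1-M) + 1*M`` and the masked edges are
    ``canny(image)*(1-M)``.
    """
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    m = mask.astype(np.float32)
    masked_gray = image.data * (1.0 - m) + 1.0 * m
    edges = canny_edges(image, sigma=sigma, low=low, high=high)
    masked_edges = edges.astype(np.float32) * (1.0 - m)
    return masked_gray.astype(np.float32), m, masked_edges


def composite_edge_map(edges: np.ndarray, predicted: np.ndarray,
                       mask: np.ndarray) -> np.ndarray:
    """Composite map: true edges outside the mask, predicted edges inside."""
    if edges.shape != predicted.shape or edges.shape != mask.shape:
        raise ValueError("shape mismatch between edge maps and mask")
    m = mask.astype(np.float32)
    return (edges.astype(np.float32) * (1.0 - m)
            + predicted.astype(np.float32) * m)


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor downsampling to feature-map resolution."""
    return np.ascontiguousarray(mask[::factor, ::factor])


def save_binary_png(arr: np.ndarray, path) -> None:
    """Store a mask or edge map as 8-bit PNG with values {0, 255}."""
    import imageio.v3 as iio
    iio.imwrite(path, (np.asarray(arr) > 0).astype(np.uint8) * 255)
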