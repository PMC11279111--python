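"""Dataset screening: find saturation-affected images, keep clean edge-rich ones.

Saturation artifacts are clusters of pixels pinned at the sensor maximum
(255 for 8-bit).  Screening uses three histogram statistics on the raw
0-255 scale: an image is *artifact-affected* when its mean and standard
deviation both exceed 20 and it actually contains saturated pixels; it is
*clean and edge-rich* when no pixel is saturated and its discrete gray-level
entropy exceeds 5 bits; everything else is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class Category(str, Enum):
    ARTIFACT_AFFECTED = "artifact_affected"
    CLEAN_EDGE_RICH = "clean_edge_rich"
    REJECTED = "rejected"


class GrayImage:
    """Single-channel image stored normalized to [0, 1].

    The saturation level (``2**bit_depth - 1`` raw) maps to exactly 1.0, so
    ``data == 1.0`` is the saturated-pixel predicate at any bit depth.
    """

    __slots__ = ("data", "bit_depth")

    def __init__(self, data: np.ndarray, bit_depth: int = 8):
        data = np.asarray(data, dtype=np.float32)
        if data.ndim != 2 or data.size == 0:
            raise ValueError("GrayImage needs a non-empty 2-D array")
        if data.min() < 0.0 or data.max() > 1.0:
            raise ValueError("GrayImage values must lie in [0, 1]")
        if bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        self.data = data
        self.bit_depth = bit_depth

    @classmethod
    def from_raw(cls, raw: np.ndarray, bit_depth: int | None = None) -> "GrayImage":
        raw = np.asarray(raw)
        if bit_depth is None:
            bit_depth = 16 if raw.dtype == np.uint16 else 8
        return cls(raw.astype(np.float32) / (2 ** bit_depth - 1), bit_depth)

    @classmethod
    def load(cls, path: str | Path) -> "GrayImage":
        import imageio.v3 as iio
        raw = np.asarray(iio.imread(path))
        if raw.ndim == 3:
            raw = raw[..., 0]
        return cls.from_raw(raw)

    def to_raw(self, bit_depth: int | None = None) -> np.ndarray:
        b = bit_depth or self.bit_depth
        levels = 2 ** b - 1
        dtype = np.uint8 if b == 8 else np.uint16
        return np.round(self.data * levels).astype(dtype)

    @property
    def shape(self):
        return self.data.shape

    def has_saturated_pixels(self) -> bool:
        return bool(np.any(self.data >= 1.0))

    def saturated_pixel_count(self) -> int:
        return int(np.count_nonzero(self.data >= 1.0))


@dataclass
class ScreeningResult:
    mean_intensity: float          # raw 0-255 scale
    std_intensity: float           # raw 0-255 scale
    entropy_bits: float
    has_saturated_pixels: bool
    saturated_pixel_count: int
    category: Category
    path: str = ""


@dataclass
class ScreeningConfig:
    """Thresholds of the printed screening rules.

    ``min_saturated_fraction`` exposes the saturated-pixel-proportion knob;
    the default 0 keeps the printed mean/std rule primary (any saturated
    pixel counts).
    """

    mean_std_threshold: float = 20.0
    entropy_threshold: float = 5.0
    min_saturated_fraction: float = 0.0


def discrete_entropy(image: GrayImage) -> float:
    """Shannon entropy (bits) of the raw gray-level histogram.

    H = -sum_i P_i log2 P_i with one bin per raw gray level (256 bins for
    8-bit); empty bins contribute nothing.  Bounded by the bit depth.
    """
    raw = image.to_raw()
    levels = 2 ** image.bit_depth
    counts = np.bincount(raw.reshape(-1), minlength=levels)
    p = counts[counts > 0] / raw.size
    return float(-(p * np.log2(p)).sum())


def classify_image(image: GrayImage,
                   config: ScreeningConfig | None = None) -> ScreeningResult:
    """Apply the screening rules to one image.

    Mean/std are computed on the raw 0-255 scale regardless of bit depth
    (16-bit data is rescaled), since the thresholds are 8-bit quantities.
    """
    cfg = config or ScreeningConfig()
    scale255 = image.data * 255.0
    mean = float(scale255.mean())
    std = float(scale255.std())
    ent = discrete_entropy(image)
    sat_count = image.saturated_pixel_count()
    sat_frac = sat_count / image.data.size
    has_sat = sat_count > 0

    if (mean > cfg.mean_std_threshold and std > cfg.mean_std_threshold
            and has_sat and sat_frac >= cfg.min_saturated_fraction):
        cat = Category.ARTIFACT_AFFECTED
    elif not has_sat and ent > cfg.entropy_threshold:
        cat = Category.CLEAN_EDGE_RICH
    else:
        cat = Category.REJECTED
    return ScreeningResult(mean, std, ent, has_sat, sat_count, cat)


def screen_dataset(images: Iterable[GrayImage | str | Path],
                   config: ScreeningConfig | None = None
                   ) -> tuple[dict[Category, int], list[ScreeningResult]]:
    """Classify a collection; unreadable files are recorded as rejected."""
    counts = {c: 0 for c in Category}
    results: list[ScreeningResult] = []
    for item in images:
        path = ""
        try:
            if isinstance(item, (str, Path)):
                path = str(item)
                item = GrayImage.load(item)
            res = classify_image(item, config)
        except Exception as exc:  # unreadable input is data, not a crash
            logger.warning("screening failed for %s: %s", path or item, exc)
            res = ScreeningResult(float("nan"), float("nan"), float("nan"),
                                  False, 0, Category.REJECTED)
        res.path = path
        counts[res.category] += 1
        results.append(res)
    return counts, results


def write_report(results: Sequence[ScreeningResult], out_csv: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([{
        "path": r.path,
        "mean": r.mean_intensity,
        "std": r.std_intensity,
        "entropy_bits": r.entropy_bits,
        "saturated_pixel_count": r.saturated_pixel_count,
        "category": r.category.value,
    } for r in results]).to_csv(out_csv, index=False)
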