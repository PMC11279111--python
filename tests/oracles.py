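"""Definitional brute-force oracles shared by the test suite.

These are deliberately naive loop implementations of the stated contracts;
the efficient library code is required to agree with them.
"""

import numpy as np


def softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def oracle_attention(feats: np.ndarray, mask: np.ndarray, k: int = 3,
                     scale: float = 10.0, eps: float = 1e-8) -> np.ndarray:
    """Patch-loop contextual attention for one (C, H, W) sample.

    Explicit patch extraction, cosine scores, scaled softmax over valid
    background patches, overlap-averaged paste of the mixed patches into
    the masked region.
    """
    c, h, w = feats.shape
    half = k // 2
    padded = np.pad(feats, ((0, 0), (half, half), (half, half)))

    def patch(y, x):
        return padded[:, y:y + k, x:x + k]

    bg = [(y, x) for y in range(half, h - half) for x in range(half, w - half)
          if not mask[y - half:y + half + 1, x - half:x + half + 1].any()]
    fg = [(y, x) for y in range(h) for x in range(w) if mask[y, x]]
    assert bg, "oracle needs at least one background patch"

    bg_patches = [patch(y, x) for (y, x) in bg]
    bg_norms = [p / max(np.linalg.norm(p), eps) for p in bg_patches]

    acc = np.zeros_like(feats, dtype=np.float64)
    cnt = np.zeros((h, w))
    for (y, x) in fg:
        f = patch(y, x)
        fn = f / max(np.linalg.norm(f), eps)
        sims = np.array([(fn * bn).sum() for bn in bg_norms])
        wts = softmax(scale * sims)
        mixed = sum(wt * bp for wt, bp in zip(wts, bg_patches))
        for dy in range(k):
            for dx in range(k):
                ty, tx = y + dy - half, x + dx - half
                if 0 <= ty < h and 0 <= tx < w:
                    acc[:, ty, tx] += mixed[:, dy, dx]
                    cnt[ty, tx] += 1

    out = feats.astype(np.float64).copy()
    m = mask > 0
    out[:, m] = acc[:, m] / cnt[m]
    return out
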