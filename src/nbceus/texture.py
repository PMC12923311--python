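"""Gray-level co-occurrence matrix (GLCM) texture of parametric maps.

Quantizes a masked parametric map to a small number of gray levels,
accumulates co-occurrence counts over a set of pixel-pair offsets, and
derives four Haralick descriptors:

* contrast    = sum p(i,j) (i-j)^2         — local intensity differences
* energy      = sum p(i,j)^2               — uniformity (angular second moment)
* correlation = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)
* homogeneity = sum p(i,j) / (1 + |i-j|)   — dominance of smooth textures

The GLCM here is mask-aware: pairs with either pixel outside the mask
(or on a missing value) are dropped rather than zero-padded, so organ
boundaries contribute no artificial texture.  The default accumulates
the four distance-1 directions into one symmetric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GLCM",
    "TextureVector",
    "DEFAULT_OFFSETS",
    "quantize_map",
    "compute_glcm",
    "haralick_features",
    "map_texture",
]

#: distance-1 displacements in the four principal directions
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

QUANT_SENTINEL = -1  # outside mask / missing value


@dataclass
class GLCM:
    probabilities: np.ndarray  # (G, G), sums to 1
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool


@dataclass(frozen=True)
class TextureVector:
    contrast: float
    energy: float
    correlation: float  # NaN when a marginal is degenerate
    homogeneity: float


def quantize_map(map_2d: np.ndarray, mask: np.ndarray | None = None, levels: int = 32) -> np.ndarray:
    """Linear min–max binning of masked finite values into 0..levels−1.

    Bins are half-open with the maximum mapped to the top level; a
    constant map maps to level 0.  Outside-mask / non-finite pixels get
    the sentinel −1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    vals = np.asarray(map_2d, dtype=float)
    if mask is None:
        mask = np.ones(vals.shape, dtype=bool)
    mask = np.asarray(mask).astype(bool) & np.isfinite(vals)
    if not np.any(mask):
        raise ValueError("no finite masked values to quantize")
    lo = vals[mask].min()
    hi = vals[mask].max()
    out = np.full(vals.shape, QUANT_SENTINEL, dtype=np.int32)
    if hi == lo:
        out[mask] = 0
        return out
    scaled = (vals[mask] - lo) / (hi - lo) * levels
    out[mask] = np.minimum(scaled.astype(np.int32), levels - 1)
    return out


def compute_glcm(
    quantized: np.ndarray,
    mask: np.ndarray | None = None,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    levels: int | None = None,
) -> GLCM:
    """Co-occurrence probabilities over all offsets, mask-aware.

    Only pairs whose both pixels are inside the mask (and not sentinel)
    count; with ``symmetric`` each pair is also counted reversed.
    """
    q = np.asarray(quantized)
    if mask is None:
        mask = q != QUANT_SENTINEL
    else:
        mask = np.asarray(mask).astype(bool) & (q != QUANT_SENTINEL)
    g = int(levels) if levels is not None else int(q[mask].max()) + 1 if np.any(mask) else 1
    counts = np.zeros((g, g), dtype=np.float64)
    h, w = q.shape
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), min(h, h - dr))
        c0 = slice(max(0, -dc), min(w, w - dc))
        r1 = slice(max(0, dr), min(h, h + dr))
        c1 = slice(max(0, dc), min(w, w + dc))
        a = q[r0, c0]
        b_ = q[r1, c1]
        valid = mask[r0, c0] & mask[r1, c1]
        if not np.any(valid):
            continue
        np.add.at(counts, (a[valid], b_[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs inside the mask")
    return GLCM(probabilities=counts / total, levels=g, offsets=tuple(offsets), symmetric=symmetric)


def haralick_features(glcm: GLCM) -> TextureVector:
    """Contrast, energy, correlation and homogeneity of one GLCM."""
    p = glcm.probabilities
    g = p.shape[0]
    i = np.arange(g)[:, None]
    j = np.arange(g)[None, :]
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    pi_ = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(g) * pi_).sum())
    mu_j = float((np.arange(g) * pj).sum())
    var_i = float(((np.arange(g) - mu_i) ** 2 * pi_).sum())
    var_j = float(((np.arange(g) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        corr = float("nan")
    else:
        corr = float(((i - mu_i) * (j - mu_j) * p).sum() / np.sqrt(var_i * var_j))
    return TextureVector(contrast=contrast, energy=energy, correlation=corr, homogeneity=homogeneity)


def map_texture(
    map_2d: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 32,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> TextureVector:
    """Quantize a parametric map and return its four Haralick features."""
    q = quantize_map(map_2d, mask, levels)
    glcm = compute_glcm(q, mask=None, offsets=offsets, symmetric=symmetric, levels=levels)
    return haralick_features(glcm)
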