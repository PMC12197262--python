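"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths (and, where possible, the libraries)
used by the implementation: morphology is done by explicit Minkowski offset
loops, Gaussian blurring by direct kernel convolution on a padded array, and
the two-way ANOVA by literal sums of squares.
"""

from __future__ import annotations

import numpy as np


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur_direct(img: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Separable direct convolution with symmetric (edge-repeating) padding."""
    k = gaussian_kernel_1d(sigma, truncate)
    radius = len(k) // 2
    out = img.astype(np.float64)
    for axis in (0, 1):
        pad = [(0, 0), (0, 0)]
        pad[axis] = (radius, radius)
        padded = np.pad(out, pad, mode="symmetric")
        acc = np.zeros_like(out)
        for i, wgt in enumerate(k):
            sl = [slice(None), slice(None)]
            sl[axis] = slice(i, i + out.shape[axis])
            acc += wgt * padded[tuple(sl)]
        out = acc
    return out


def unsharp_direct(
    img: np.ndarray, radius: float, amount: float, threshold: float
) -> np.ndarray:
    blurred = gaussian_blur_direct(img, radius)
    detail = img - blurred
    out = np.where(np.abs(detail) >= threshold, img + amount * detail, img)
    return np.clip(out, 0.0, 255.0)


def disk_offsets(r: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= r * r
    ]


def erode_bf(mask: np.ndarray, r: int) -> np.ndarray:
    """Minkowski erosion: a pixel stays iff every offset lands on foreground.

    Out-of-bounds counts as background, so border pixels needing an outside
    offset are removed.
    """
    h, w = mask.shape
    out = np.ones_like(mask, dtype=bool)
    for dr, dc in disk_offsets(r):
        shifted = np.zeros((h, w), dtype=bool)
        rs = slice(max(0, -dr), min(h, h - dr))
        rd = slice(max(0, dr), min(h, h + dr))
        cs = slice(max(0, -dc), min(w, w - dc))
        cd = slice(max(0, dc), min(w, w + dc))
        shifted[rs, cs] = mask.astype(bool)[rd, cd]
        out &= shifted
    return out


def dilate_bf(mask: np.ndarray, r: int) -> np.ndarray:
    """Minkowski dilation: union of the mask translated by every offset."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for dr, dc in disk_offsets(r):
        rs = slice(max(0, dr), min(h, h + dr))
        rd = slice(max(0, -dr), min(h, h - dr))
        cs = slice(max(0, dc), min(w, w + dc))
        cd = slice(max(0, -dc), min(w, w - dc))
        out[rs, cs] |= mask.astype(bool)[rd, cd]
    return out


def open_close_bf(mask: np.ndarray, r: int) -> np.ndarray:
    opened = dilate_bf(erode_bf(mask, r), r)
    return erode_bf(dilate_bf(opened, r), r)


def best_match_jaccard(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Mean over a's labels of the best Jaccard against any label of b."""
    n_a, n_b = int(labels_a.max()), int(labels_b.max())
    cont = np.zeros((n_a + 1, n_b + 1))
    np.add.at(cont, (labels_a.ravel(), labels_b.ravel()), 1)
    sa = cont.sum(axis=1)
    sb = cont.sum(axis=0)
    best = []
    for i in range(1, n_a + 1):
        inter = cont[i, 1:]
        union = sa[i] + sb[1:] - inter
        best.append(float((inter / np.maximum(union, 1)).max()))
    return float(np.mean(best))


def icc_2_1_bf(m: np.ndarray) -> float:
    """ICC(2,1) from literal two-way ANOVA sums of squares (loops, no vector tricks)."""
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sst = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
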