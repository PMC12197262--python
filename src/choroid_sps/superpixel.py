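"""From-scratch SLIC superpixel segmentation for grayscale images.

SLIC is localized k-means in the joint (row, col, intensity) space.  With a
requested superpixel count K on an H×W image, cluster centers start on a
regular grid with spacing S = sqrt(H·W/K), are nudged to the lowest-gradient
pixel in their 3×3 neighborhood, and then iterate: each center claims pixels
inside its 2S×2S search window, a pixel going to the center minimizing

    D = sqrt(d_c^2 + (d_s / S)^2 * m^2)

where d_c is the intensity difference (0–255 scale), d_s the Euclidean
spatial distance, and m the compactness weight.  After the iterations,
4-connectivity is enforced by merging undersized orphan components into the
adjacent component with the longest shared border, and labels are renumbered
densely 1..N.  The result is an exact partition of the pixel domain.

The whole procedure is deterministic; ``seed`` is accepted for forward
compatibility but is a documented no-op (grid initialization has no
randomness).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import BinaryMask, GrayImage

__all__ = [
    "SlicParams",
    "SuperpixelLabelMap",
    "slic_segment",
    "label_boundaries",
    "write_labelmap",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SlicParams:
    """Tunables of the SLIC partition.

    n_segments
        Requested superpixel count K; the realized count N may differ.
    compactness
        Shape-regularity weight m on the 0–255 intensity scale; larger values
        give squarer superpixels, smaller values hug intensity edges.
    n_iters
        Number of assignment/update sweeps (10 suffices for convergence).
    min_size_factor
        Fraction of the mean superpixel size below which a 4-connected
        orphan component is merged into a neighbor.
    """

    n_segments: int = 300
    compactness: float = 20.0
    n_iters: int = 10
    min_size_factor: float = 0.25

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ParameterError(f"n_segments must be >= 1, got {self.n_segments}")
        if self.compactness <= 0:
            raise ParameterError(f"compactness must be > 0, got {self.compactness}")
        if self.n_iters < 1:
            raise ParameterError(f"n_iters must be >= 1, got {self.n_iters}")
        if not (0 < self.min_size_factor < 1):
            raise ParameterError(
                f"min_size_factor must be in (0, 1), got {self.min_size_factor}"
            )


@dataclass(frozen=True)
class SuperpixelLabelMap:
    """A dense partition of the image domain into superpixels labeled 1..N."""

    labels: np.ndarray
    mean_intensity: np.ndarray  # index i-1 holds the mean intensity of label i

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        object.__setattr__(self, "labels", lab.astype(np.int32))
        object.__setattr__(
            self, "mean_intensity", np.asarray(self.mean_intensity, dtype=np.float64)
        )

    @property
    def n_superpixels(self) -> int:
        return int(self.mean_intensity.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def sizes(self) -> np.ndarray:
        """Pixel count of each label (index i-1 for label i)."""
        return np.bincount(self.labels.ravel(), minlength=self.n_superpixels + 1)[1:]


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    # sum of squared forward differences; the last row/col reuse a zero diff
    gr = np.zeros_like(img)
    gc = np.zeros_like(img)
    gr[:-1, :] = np.diff(img, axis=0)
    gc[:, :-1] = np.diff(img, axis=1)
    return gr**2 + gc**2


def _init_centers(img: np.ndarray, k: int) -> np.ndarray:
    """Grid-initialized centers, each moved to the 3×3 lowest-gradient pixel.

    Returns an array of shape (N0, 3) holding (row, col, intensity).
    """
    h, w = img.shape
    s = np.sqrt(h * w / k)
    step = max(1, round(s))
    rows = np.arange(step // 2, h, step)
    cols = np.arange(step // 2, w, step)
    if len(rows) * len(cols) < k:
        # integer rounding lost centers (small K); fall back to per-axis
        # counts with fractional spacing so at least K centers exist
        nr = max(1, round(np.sqrt(k * h / w)))
        nc = int(np.ceil(k / nr))
        rows = ((np.arange(nr) + 0.5) * h / nr).astype(int).clip(0, h - 1)
        cols = ((np.arange(nc) + 0.5) * w / nc).astype(int).clip(0, w - 1)
    grad = _gradient_magnitude(img)
    centers = []
    for r in rows:
        for c in cols:
            r0, r1 = max(0, r - 1), min(h, r + 2)
            c0, c1 = max(0, c - 1), min(w, c + 2)
            win = grad[r0:r1, c0:c1]
            dr, dc = np.unravel_index(np.argmin(win), win.shape)
            rr, cc = r0 + dr, c0 + dc
            centers.append((float(rr), float(cc), img[rr, cc]))
    return np.array(centers, dtype=np.float64)


def _assign(img: np.ndarray, centers: np.ndarray, s: float, m: float):
    """One assignment sweep: each pixel to the nearest center in D.

    Centers are visited in increasing index order with a strict-< update, so
    on a tie in D the lower center index wins.
    """
    h, w = img.shape
    dist = np.full((h, w), np.inf)
    lab = np.full((h, w), -1, dtype=np.int32)
    win = int(np.ceil(s))
    m2s2 = (m / s) ** 2
    for k, (cr, cc, ci) in enumerate(centers):
        r0 = max(0, int(np.floor(cr)) - win)
        r1 = min(h, int(np.floor(cr)) + win + 1)
        c0 = max(0, int(np.floor(cc)) - win)
        c1 = min(w, int(np.floor(cc)) + win + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        dc2 = (img[r0:r1, c0:c1] - ci) ** 2
        drow = (np.arange(r0, r1, dtype=np.float64) - cr) ** 2
        dcol = (np.arange(c0, c1, dtype=np.float64) - cc) ** 2
        d2 = dc2 + (drow[:, None] + dcol[None, :]) * m2s2
        sub = dist[r0:r1, c0:c1]
        better = d2 < sub
        sub[better] = d2[better]
        lab[r0:r1, c0:c1][better] = k
    # pixels missed by every window (possible only in pathological geometries)
    if (lab < 0).any():
        miss = np.argwhere(lab < 0)
        d = (
            (miss[:, 0:1] - centers[None, :, 0]) ** 2
            + (miss[:, 1:2] - centers[None, :, 1]) ** 2
        ) * m2s2 + (img[miss[:, 0], miss[:, 1], None] - centers[None, :, 2]) ** 2
        lab[miss[:, 0], miss[:, 1]] = np.argmin(d, axis=1)
    return lab


def _update_centers(img: np.ndarray, lab: np.ndarray, centers: np.ndarray) -> np.ndarray:
    h, w = img.shape
    n = len(centers)
    flat = lab.ravel()
    counts = np.bincount(flat, minlength=n)
    rr, cc = np.indices((h, w))
    sums_r = np.bincount(flat, weights=rr.ravel(), minlength=n)
    sums_c = np.bincount(flat, weights=cc.ravel(), minlength=n)
    sums_i = np.bincount(flat, weights=img.ravel(), minlength=n)
    out = centers.copy()
    nz = counts > 0
    out[nz, 0] = sums_r[nz] / counts[nz]
    out[nz, 1] = sums_c[nz] / counts[nz]
    out[nz, 2] = sums_i[nz] / counts[nz]
    return out


def _enforce_connectivity(lab: np.ndarray, min_size_factor: float) -> np.ndarray:
    """Merge undersized 4-connected components into adjacent components.

    The merge target is the adjacent component sharing the longest border,
    preferring components at least as large as the orphan; ties break toward
    the lower superpixel label.
    """
    h, w = lab.shape
    comp = np.zeros((h, w), dtype=np.int32)
    comp_label: list[int] = [0]  # comp id -> superpixel label (0 unused)
    next_id = 1
    for k in np.unique(lab):
        cc, n = ndimage.label(lab == k, structure=_FOUR_CONN)
        comp[cc > 0] = cc[cc > 0] + (next_id - 1)
        comp_label.extend([int(k)] * n)
        next_id += n

    n_labels = len(np.unique(lab))
    min_size = min_size_factor * (h * w / n_labels)
    sizes = np.bincount(comp.ravel(), minlength=next_id)

    pix: dict[int, np.ndarray] = {}
    order = np.argsort(comp.ravel(), kind="stable")
    bounds = np.searchsorted(comp.ravel()[order], np.arange(next_id + 1))
    for cid in range(1, next_id):
        pix[cid] = order[bounds[cid] : bounds[cid + 1]]

    alias = np.arange(next_id)  # comp id -> current comp id after merges

    small = sorted(
        (cid for cid in range(1, next_id) if sizes[cid] < min_size),
        key=lambda cid: (sizes[cid], cid),
    )
    for cid in small:
        if sizes[cid] >= min_size:  # grew by receiving a merge
            continue
        flat_idx = pix[cid]
        rs, cs = np.unravel_index(flat_idx, (h, w))
        # count shared-border pixels with each neighboring component
        contact: dict[int, int] = {}
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = rs + dr, cs + dc
            ok = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
            ncomp = alias[comp[nr[ok], nc[ok]]]
            for v in ncomp[ncomp != alias[cid]]:
                contact[int(v)] = contact.get(int(v), 0) + 1
        if not contact:
            continue  # component spans a full image region with no neighbor
        larger = {c: n for c, n in contact.items() if sizes[c] >= sizes[cid]}
        pool = larger if larger else contact
        target = min(pool, key=lambda c: (-pool[c], comp_label[c], c))
        comp[rs, cs] = target
        alias[alias == alias[cid]] = target
        pix[target] = np.concatenate([pix[target], flat_idx])
        sizes[target] += sizes[cid]
        sizes[cid] = 0

    # every surviving component becomes its own label (a superpixel whose
    # assignment split into several islands yields several superpixels),
    # renumbered densely 1..N in component order
    uniq, inv = np.unique(comp, return_inverse=True)
    return (inv + 1).astype(np.int32).reshape(h, w)


def slic_segment(
    img: GrayImage, params: SlicParams | None = None, seed: int = 0
) -> SuperpixelLabelMap:
    """Partition a grayscale image into SLIC superpixels.

    Parameters
    ----------
    img
        Grayscale image on the 0–255 scale.
    params
        SLIC tunables; defaults to :class:`SlicParams()`.
    seed
        Accepted for interface stability; plain SLIC is fully deterministic,
        so this is a no-op.

    Returns
    -------
    SuperpixelLabelMap
        Dense labels 1..N with per-label mean intensities.  N may differ
        from ``params.n_segments``.
    """
    del seed  # deterministic algorithm; see module docstring
    params = params or SlicParams()
    px = img.pixels
    h, w = px.shape
    if params.n_segments > h * w:
        raise ParameterError(
            f"n_segments={params.n_segments} exceeds pixel count {h * w}"
        )
    if h * w == 1 or params.n_segments == 1:
        labels = np.ones((h, w), dtype=np.int32)
        return SuperpixelLabelMap(labels, np.array([px.mean()]))

    s = np.sqrt(h * w / params.n_segments)
    centers = _init_centers(px, params.n_segments)
    lab = None
    for _ in range(params.n_iters):
        lab = _assign(px, centers, s, params.compactness)
        centers = _update_centers(px, lab, centers)
    lab = _enforce_connectivity(lab, params.min_size_factor)

    n = int(lab.max())
    counts = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    sums = np.bincount(lab.ravel(), weights=px.ravel(), minlength=n + 1)[1:]
    assert (counts > 0).all(), "partition must cover every label"
    return SuperpixelLabelMap(lab, sums / counts)


def label_boundaries(lmap: SuperpixelLabelMap) -> BinaryMask:
    """Mask the pixels that have a 4-neighbor with a different label."""
    lab = lmap.labels
    b = np.zeros(lab.shape, dtype=bool)
    b[:-1, :] |= lab[:-1, :] != lab[1:, :]
    b[1:, :] |= lab[1:, :] != lab[:-1, :]
    b[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    b[:, 1:] |= lab[:, 1:] != lab[:, :-1]
    return BinaryMask(b.astype(np.uint8))


def write_labelmap(
    lmap: SuperpixelLabelMap,
    path: str | os.PathLike,
    sidecar_path: str | os.PathLike | None = None,
) -> None:
    """Serialize labels as a 16-bit raster plus an optional sidecar CSV.

    The sidecar has one row per label: ``label,size_px,mean_intensity``.
    """
    import tifffile
    from PIL import Image

    if lmap.n_superpixels > 65535:
        raise ParameterError("label map exceeds 16-bit range")
    data = lmap.labels.astype(np.uint16)
    path = os.fspath(path)
    if os.path.splitext(path)[1].lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data, mode="I;16").save(path)
    if sidecar_path is not None:
        sizes = lmap.sizes()
        with open(sidecar_path, "w") as fh:
            fh.write("label,size_px,mean_intensity\n")
            for i in range(lmap.n_superpixels):
                fh.write(f"{i + 1},{sizes[i]},{lmap.mean_intensity[i]:.6g}\n")
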