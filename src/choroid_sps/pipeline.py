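"""The SpS processing chain: sharpen → segment → select → smooth → measure.

Given a grayscale OCT B-scan the pipeline

1. enhances edges by unsharp masking (Gaussian blur subtraction),
2. partitions the sharpened image into SLIC superpixels,
3. builds a binary mask from a selected subset of superpixels (an explicit
   label list, or labels chosen automatically by overlap with a reference
   mask — the reproducible stand-in for interactive clicking),
4. smooths the mask by morphological opening then closing with a disk, and
5. reports the choroidal area CA (set-pixel count, px²) and the choroidal
   optical image density COID (mean intensity of the original image over
   the smoothed mask).

COID is measured on the *original* image by default: sharpening exists to
help the segmentation find boundaries, while the density metric should
reflect the raw signal.  ``SpsConfig.coid_on_sharpened`` preserves the
alternative reading.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .errors import ParameterError, SelectionError, UndefinedMetricError
from .image_io import BinaryMask, GrayImage
from .superpixel import SlicParams, SuperpixelLabelMap, slic_segment

__all__ = [
    "SpsConfig",
    "ChoroidMetrics",
    "sharpen",
    "disk_element",
    "smooth_mask",
    "mask_from_selection",
    "auto_select",
    "compute_ca",
    "compute_coid",
    "run_sps",
    "render_overlays",
]


@dataclass(frozen=True)
class SpsConfig:
    """Everything the operator would predefine before processing a scan.

    sharpen_radius / sharpen_amount / sharpen_threshold
        Unsharp-masking controls: Gaussian σ in px, overshoot gain, and the
        minimum |detail| (0–255 units) below which a pixel is left untouched.
    slic
        Superpixel tunables (see :class:`SlicParams`).
    disk_radius
        Radius r (px) of the disk structuring element used for the
        opening-then-closing smoothing of the selected mask.
    selection_overlap
        Minimum fraction of a superpixel's area inside a reference mask for
        it to be auto-selected.
    coid_on_sharpened
        Measure COID on the sharpened image instead of the original.
    """

    sharpen_radius: float = 1.0
    sharpen_amount: float = 0.8
    sharpen_threshold: float = 0.0
    slic: SlicParams = field(default_factory=SlicParams)
    disk_radius: int = 5
    selection_overlap: float = 0.5
    coid_on_sharpened: bool = False

    def __post_init__(self) -> None:
        if self.sharpen_radius <= 0:
            raise ParameterError(f"sharpen_radius must be > 0, got {self.sharpen_radius}")
        if self.sharpen_amount < 0:
            raise ParameterError(f"sharpen_amount must be >= 0, got {self.sharpen_amount}")
        if not (0 <= self.sharpen_threshold <= 255):
            raise ParameterError(
                f"sharpen_threshold must be in [0, 255], got {self.sharpen_threshold}"
            )
        if self.disk_radius < 0:
            raise ParameterError(f"disk_radius must be >= 0, got {self.disk_radius}")
        if not (0 < self.selection_overlap <= 1):
            raise ParameterError(
                f"selection_overlap must be in (0, 1], got {self.selection_overlap}"
            )

    # -- flat key=value serialization (mirrors the config-file dialect) ----

    _SLIC_KEYS = ("n_segments", "compactness", "n_iters", "min_size_factor")

    def to_flat_dict(self) -> dict:
        d = asdict(self)
        slic = d.pop("slic")
        d.update(slic)
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "SpsConfig":
        d = dict(d)
        slic_kwargs = {k: d.pop(k) for k in cls._SLIC_KEYS if k in d}
        known = {f for f in cls.__dataclass_fields__ if f != "slic"}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(slic=SlicParams(**slic_kwargs), **d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class ChoroidMetrics:
    """Per-image outcome: area in px² and mean intensity of the region."""

    ca_px2: int
    coid: float


def sharpen(
    img: GrayImage, radius: float = 1.0, amount: float = 0.8, threshold: float = 0.0
) -> GrayImage:
    """Unsharp masking: I + amount·(I − Gaussian_σ(I)), thresholded on |detail|.

    The blur uses σ = ``radius`` truncated at 4σ with a reflective border.
    Pixels whose |detail| falls below ``threshold`` are left unchanged; the
    result is clamped to [0, 255].
    """
    if radius <= 0:
        raise ParameterError(f"radius must be > 0, got {radius}")
    px = img.pixels
    blurred = ndimage.gaussian_filter(px, sigma=radius, mode="reflect", truncate=4.0)
    detail = px - blurred
    out = np.where(np.abs(detail) >= threshold, px + amount * detail, px)
    return GrayImage(np.clip(out, 0.0, 255.0))


def disk_element(r: int) -> np.ndarray:
    """Closed Euclidean disk of radius r as a boolean (2r+1)² footprint.

    An offset (dr, dc) belongs to the disk iff dr² + dc² ≤ r²; r = 0 is the
    single center pixel and r = 1 the 5-pixel cross.
    """
    if r < 0:
        raise ParameterError(f"disk radius must be >= 0, got {r}")
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr**2 + dc**2) <= r**2


def smooth_mask(mask: BinaryMask, r: int) -> BinaryMask:
    """Morphological opening followed by closing with a disk of radius r.

    Out-of-bounds pixels count as background for both erosion and dilation,
    so regions touching the image border are treated like regions bordering
    background. r = 0 is the identity.
    """
    if r < 0:
        raise ParameterError(f"disk radius must be >= 0, got {r}")
    if r == 0:
        return mask
    st = disk_element(r)
    m = mask.astype_bool()
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(m, structure=st, border_value=0),
        structure=st,
        border_value=0,
    )
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(opened, structure=st, border_value=0),
        structure=st,
        border_value=0,
    )
    return BinaryMask(closed.astype(np.uint8))


def mask_from_selection(
    lmap: SuperpixelLabelMap, selected: set[int] | list[int] | tuple[int, ...]
) -> BinaryMask:
    """Indicator mask of the union of the selected superpixels."""
    sel = set(int(s) for s in selected)
    bad = [s for s in sel if not (1 <= s <= lmap.n_superpixels)]
    if bad:
        raise SelectionError(
            f"selected labels {sorted(bad)} outside 1..{lmap.n_superpixels}"
        )
    if not sel:
        return BinaryMask(np.zeros(lmap.shape, dtype=np.uint8))
    lut = np.zeros(lmap.n_superpixels + 1, dtype=np.uint8)
    lut[list(sel)] = 1
    return BinaryMask(lut[lmap.labels])


def auto_select(
    lmap: SuperpixelLabelMap, reference: BinaryMask, overlap: float = 0.5
) -> set[int]:
    """Labels whose fraction of pixels inside ``reference`` is ≥ ``overlap``.

    A deterministic, reproducible stand-in for interactive click selection.
    """
    if reference.shape != lmap.shape:
        raise SelectionError(
            f"reference shape {reference.shape} != label map shape {lmap.shape}"
        )
    if not (0 < overlap <= 1):
        raise ParameterError(f"overlap must be in (0, 1], got {overlap}")
    n = lmap.n_superpixels
    flat = lmap.labels.ravel()
    total = np.bincount(flat, minlength=n + 1)[1:]
    inside = np.bincount(
        flat, weights=reference.pixels.ravel().astype(np.float64), minlength=n + 1
    )[1:]
    frac = inside / total
    return set(int(i + 1) for i in np.nonzero(frac >= overlap)[0])


def compute_ca(mask: BinaryMask) -> int:
    """Choroidal area: the count of set pixels (px²)."""
    return int(mask.pixels.sum())


def compute_coid(img: GrayImage, mask: BinaryMask) -> float:
    """Choroidal optical image density: mean intensity over the set pixels."""
    if img.shape != mask.shape:
        raise UndefinedMetricError(
            f"image shape {img.shape} != mask shape {mask.shape}"
        )
    sel = mask.astype_bool()
    if not sel.any():
        raise UndefinedMetricError("COID is undefined for an empty mask")
    return float(img.pixels[sel].mean())


def run_sps(
    img: GrayImage,
    cfg: SpsConfig | None = None,
    selection: set[int] | list[int] | BinaryMask | None = None,
    seed: int = 0,
) -> tuple[SuperpixelLabelMap, BinaryMask, ChoroidMetrics]:
    """Run the full chain on one scan and return (label map, Ms, metrics).

    ``selection`` is either an explicit set of superpixel labels or a
    reference :class:`BinaryMask` from which labels are auto-selected at the
    configured overlap threshold.
    """
    cfg = cfg or SpsConfig()
    if selection is None:
        raise SelectionError("a selection (label set or reference mask) is required")
    sharpened = sharpen(
        img, cfg.sharpen_radius, cfg.sharpen_amount, cfg.sharpen_threshold
    )
    lmap = slic_segment(sharpened, cfg.slic, seed=seed)
    if isinstance(selection, BinaryMask):
        labels = auto_select(lmap, selection, cfg.selection_overlap)
    else:
        labels = set(selection)
    mask = mask_from_selection(lmap, labels)
    ms = smooth_mask(mask, cfg.disk_radius)
    measured = sharpened if cfg.coid_on_sharpened else img
    metrics = ChoroidMetrics(ca_px2=compute_ca(ms), coid=compute_coid(measured, ms))
    return lmap, ms, metrics


def render_overlays(
    img: GrayImage, ms: BinaryMask
) -> tuple[GrayImage, np.ndarray, np.ndarray]:
    """The three standard visualizations of the smoothed region Ms.

    Returns
    -------
    (region, blend, green)
        ``region`` — the image with everything outside Ms zeroed;
        ``blend`` — RGB, the mask shown semi-transparently (α = 0.5, white
        tint) on the image; ``green`` — RGB, masked pixels blended halfway
        toward fluorescent green (0, 255, 0).
    """
    if img.shape != ms.shape:
        raise UndefinedMetricError(f"image shape {img.shape} != mask shape {ms.shape}")
    m = ms.astype_bool()
    region = GrayImage(img.pixels * ms.pixels)

    gray = img.pixels
    rgb = np.repeat(gray[..., None], 3, axis=2)
    blend = rgb.copy()
    blend[m] = 0.5 * rgb[m] + 0.5 * 255.0

    green = rgb.copy()
    tint = np.array([0.0, 255.0, 0.0])
    green[m] = 0.5 * rgb[m] + 0.5 * tint
    return region, blend, green
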