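"""Synthetic OCT B-scan phantoms with known choroid geometry and intensity.

Clinical B-scans are confidential, so every stage of the pipeline is
exercised on layered phantoms that emulate the gross appearance of a macular
B-scan: dark vitreous at the top, a bright retinal complex ending in a
brighter RPE-like line, a choroid band containing dark elliptical vessel
lumens, and darker sclera below.  Layer boundaries undulate as a two-term
random-phase sinusoid, and the whole image receives mean-preserving
multiplicative speckle: each pixel is multiplied by g ~ Gamma(L, 1/L)
(mean 1, variance 1/L), the standard L-look model for coherent imaging.

Each phantom carries its ground truth: the exact choroid-band mask, its
pixel area, and the expected pre-speckle band mean

    (1 − f)·stroma + f·lumen

with f the realized lumen fraction — the quantities the pipeline's CA and
COID should recover.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .image_io import BinaryMask, GrayImage
from .pipeline import compute_ca

__all__ = ["PhantomParams", "Phantom", "generate_phantom", "generate_cohort"]

_REF_HEIGHT = 992  # geometry defaults are stated at the nominal scan size


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensities and noise of one phantom B-scan.

    Intensities are on the 0–255 scale; the stated defaults describe the
    nominal 1024 × 992 px export.  ``choroid_mean_intensity`` is the stromal
    level before vessels and speckle; ``vessel_fraction`` is the target
    fraction of the choroid band occupied by lumens at ``vessel_intensity``.
    ``speckle_looks`` is the L of the L-look multiplicative speckle model
    (larger L → weaker noise).
    """

    height: int = 992
    width: int = 1024
    retina_top: int = 180
    retina_thickness: int = 160
    choroid_thickness_mean: int = 220
    choroid_mean_intensity: float = 110.0
    vessel_intensity: float = 40.0
    vessel_fraction: float = 0.25
    boundary_waviness: float = 8.0
    speckle_looks: float = 6.0
    background_intensity: float = 15.0
    retina_intensity: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "choroid_mean_intensity",
            "vessel_intensity",
            "background_intensity",
            "retina_intensity",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ParameterError(f"{name} must be in [0, 255], got {v}")
        if not (0 <= self.vessel_fraction < 1):
            raise ParameterError(
                f"vessel_fraction must be in [0, 1), got {self.vessel_fraction}"
            )
        if self.speckle_looks < 1:
            raise ParameterError(
                f"speckle_looks must be >= 1, got {self.speckle_looks}"
            )
        bottom = (
            self.retina_top
            + self.retina_thickness
            + self.choroid_thickness_mean
            + 2 * self.boundary_waviness
        )
        if self.retina_top < 1 or bottom >= self.height:
            raise ParameterError(
                f"layer geometry (bottom ~{bottom:g}) does not fit in height "
                f"{self.height}"
            )

    @classmethod
    def scaled(cls, height: int, width: int, **overrides) -> "PhantomParams":
        """Defaults with the layer geometry scaled linearly to a new size."""
        f = height / _REF_HEIGHT
        base = dict(
            height=height,
            width=width,
            retina_top=max(2, round(180 * f)),
            retina_thickness=max(2, round(160 * f)),
            choroid_thickness_mean=max(4, round(220 * f)),
            boundary_waviness=max(1.0, 8.0 * f),
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class Phantom:
    """A phantom image plus its ground truth."""

    image: GrayImage
    truth_mask: BinaryMask
    truth_area_px2: int
    truth_mean_intensity: float
    params: PhantomParams


def _wavy_boundary(
    base: float, width: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-term random-phase sinusoid around ``base``, one value per column."""
    x = np.arange(width) / max(width, 1)
    f1, f2 = rng.uniform(1.0, 2.5), rng.uniform(3.0, 5.0)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    wave = 0.65 * np.sin(2 * np.pi * f1 * x + p1) + 0.35 * np.sin(
        2 * np.pi * f2 * x + p2
    )
    return base + amplitude * wave


def _place_vessels(
    stroma: np.ndarray,
    band: np.ndarray,
    p: PhantomParams,
    rng: np.random.Generator,
) -> float:
    """Draw elliptical lumens inside the band until the target fraction.

    Returns the realized lumen fraction of the band.  Ellipse semi-axes are
    sized so each lumen adds roughly 1–2 % of the band area, keeping the
    overshoot within the ±10 % tolerance on ``vessel_fraction``.
    """
    if p.vessel_fraction == 0:
        return 0.0
    area = int(band.sum())
    rows, cols = np.nonzero(band)
    thickness = max(4.0, p.choroid_thickness_mean)
    lumen = np.zeros_like(band)
    rr_grid, cc_grid = np.indices(band.shape)
    target = p.vessel_fraction
    for _ in range(10_000):
        f = lumen.sum() / area
        if f >= target * 0.95:
            break
        i = rng.integers(len(rows))
        cy, cx = rows[i], cols[i]
        a = rng.uniform(0.10, 0.22) * thickness  # vertical semi-axis
        b = a * rng.uniform(1.2, 2.2)  # horizontal semi-axis
        r0 = max(0, int(cy - a - 1))
        r1 = min(band.shape[0], int(cy + a + 2))
        c0 = max(0, int(cx - b - 1))
        c1 = min(band.shape[1], int(cx + b + 2))
        ell = (
            ((rr_grid[r0:r1, c0:c1] - cy) / a) ** 2
            + ((cc_grid[r0:r1, c0:c1] - cx) / b) ** 2
        ) <= 1.0
        lumen[r0:r1, c0:c1] |= ell & band[r0:r1, c0:c1]
    stroma[lumen.astype(bool)] = p.vessel_intensity
    return float(lumen.sum() / area)


def generate_phantom(params: PhantomParams | None = None) -> Phantom:
    """Build one phantom B-scan from its parameters (fully seeded)."""
    p = params or PhantomParams()
    rng = np.random.default_rng(p.seed)
    h, w = p.height, p.width

    upper = _wavy_boundary(
        p.retina_top + p.retina_thickness, w, p.boundary_waviness, rng
    )
    # constant-thickness undulating band: each column holds exactly
    # choroid_thickness_mean integer rows, so the truth area is
    # thickness * width independent of the random phases
    lower = upper + p.choroid_thickness_mean

    rr = np.arange(h)[:, None].astype(np.float64)
    img = np.full((h, w), p.background_intensity)
    retina = (rr >= p.retina_top) & (rr < upper[None, :])
    img[retina] = p.retina_intensity
    rpe_rows = max(2, round(0.008 * p.height))
    rpe = (rr >= upper[None, :] - rpe_rows) & (rr < upper[None, :]) & retina
    img[rpe] = min(255.0, p.retina_intensity + 40.0)

    band = (rr >= upper[None, :]) & (rr < lower[None, :])
    img[band] = p.choroid_mean_intensity
    f_actual = _place_vessels(img, band, p, rng)

    g = rng.gamma(shape=p.speckle_looks, scale=1.0 / p.speckle_looks, size=(h, w))
    img = np.clip(img * g, 0.0, 255.0)

    truth = BinaryMask(band.astype(np.uint8))
    truth_mean = (
        1.0 - f_actual
    ) * p.choroid_mean_intensity + f_actual * p.vessel_intensity
    return Phantom(
        image=GrayImage(img),
        truth_mask=truth,
        truth_area_px2=compute_ca(truth),
        truth_mean_intensity=float(truth_mean),
        params=p,
    )


def generate_cohort(
    n_per_group: int,
    healthy: PhantomParams | None = None,
    diabetic: PhantomParams | None = None,
    seed: int = 0,
    thickness_sd: float | None = None,
    intensity_sd: float = 4.0,
) -> tuple[list[Phantom], pd.DataFrame]:
    """Simulate a two-group cohort of phantoms with per-subject jitter.

    Each subject's choroid thickness and stromal intensity are drawn from
    normal distributions around the group parameters (``thickness_sd``
    defaults to 8 % of the group mean thickness).  Returns the phantoms and
    a measurement-table skeleton holding the truth values and empty
    ``ca_px2``/``coid`` columns for the pipeline to fill.
    """
    if n_per_group < 1:
        raise ParameterError(f"n_per_group must be >= 1, got {n_per_group}")
    healthy = healthy or PhantomParams()
    diabetic = diabetic or replace(
        healthy,
        choroid_thickness_mean=round(0.6 * healthy.choroid_thickness_mean),
        choroid_mean_intensity=min(255.0, healthy.choroid_mean_intensity + 25.0),
    )
    rng = np.random.default_rng(seed)
    phantoms: list[Phantom] = []
    rows = []
    for group, base in (("healthy", healthy), ("diabetic", diabetic)):
        t_sd = (
            0.08 * base.choroid_thickness_mean if thickness_sd is None else thickness_sd
        )
        for i in range(n_per_group):
            thick = int(
                np.clip(
                    round(rng.normal(base.choroid_thickness_mean, t_sd)),
                    4,
                    base.height - base.retina_top - base.retina_thickness
                    - 2 * base.boundary_waviness - 1,
                )
            )
            inten = float(
                np.clip(rng.normal(base.choroid_mean_intensity, intensity_sd), 1, 254)
            )
            # seed derived from the jittered parameters: zero jitter gives a
            # group of identical phantoms sharing their truth values
            blob = f"{seed}|{group}|{thick}|{inten:.6f}".encode()
            sub_seed = int.from_bytes(
                hashlib.sha256(blob).digest()[:4], "big"
            ) % (2**31 - 1)
            params = replace(
                base,
                choroid_thickness_mean=thick,
                choroid_mean_intensity=inten,
                seed=sub_seed,
            )
            ph = generate_phantom(params)
            phantoms.append(ph)
            rows.append(
                {
                    "image_id": f"{group}_{i:03d}",
                    "group": group,
                    "examiner_id": "E1",
                    "session_id": "S1",
                    "ca_px2": np.nan,
                    "coid": np.nan,
                    "truth_area_px2": ph.truth_area_px2,
                    "truth_mean_intensity": ph.truth_mean_intensity,
                }
            )
    return phantoms, pd.DataFrame(rows)
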