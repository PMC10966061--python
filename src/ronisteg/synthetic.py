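"""Synthetic abdominal-slice phantoms and synthetic patient records.

Stands in for clinical CT/MR slices so the whole pipeline is testable
without any data download: near-black background with faint sensor noise,
a handful of bright, textured, elliptical organ-like blobs with steep
edges, and the exact analytic foreground mask as ground truth. CT-style
frames are 512x512 at 16 bit, MR-style 256x256 at 12 bit. The blob model
is deliberately geometric rather than anatomical - the embedding method
only cares about a compact bright foreground and a dark background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import MedicalImage, Modality
from .mask import BinaryMask

__all__ = ["PhantomSpec", "generate_phantom", "generate_patient_record"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic slice.

    background_noise_level bounds the background amplitude at
    ``level * R * 0.01`` (level 0.3 -> 0.3% of the dynamic range: dark but
    not digitally zero, like air in a CT). target_foreground is the
    acceptable range for the blob coverage fraction; the generator rescales
    blob axes (up to 10 attempts) to land inside it.
    """

    shape: tuple[int, int] = (512, 512)
    bit_depth: int = 16
    modality_style: Modality = Modality.CT
    n_blobs: int = 3
    background_noise_level: float = 0.3
    seed: int = 0
    target_foreground: tuple[float, float] = (0.3, 0.6)

    def __post_init__(self) -> None:
        if self.shape[0] % 4 or self.shape[1] % 4:
            raise ValueError("phantom shape must be divisible by 4")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        if self.background_noise_level < 0:
            raise ValueError("background_noise_level must be >= 0")

    @classmethod
    def ct(cls, seed: int = 0, **kw) -> "PhantomSpec":
        return cls(shape=(512, 512), bit_depth=16, modality_style=Modality.CT,
                   seed=seed, **kw)

    @classmethod
    def mr(cls, seed: int = 0, **kw) -> "PhantomSpec":
        return cls(shape=(256, 256), bit_depth=12, modality_style=Modality.MR,
                   seed=seed, **kw)


def _blob_field(shape, params, edge_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Analytic blob union: (normalized intensity profile, ground-truth mask).

    Each blob is a rotated ellipse; rho is the elliptical radius (1 at the
    nominal edge). Intensity inside is >= 0.32 of peak, tapering off to 0
    within ``edge_px`` pixels beyond rho = 1, so the thresholded contour
    tracks the ground-truth edge closely.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    profile = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for (cy, cx, a, b, theta) in params:
        ct, st = np.cos(theta), np.sin(theta)
        u = ((xx - cx) * ct + (yy - cy) * st) / a
        v = (-(xx - cx) * st + (yy - cy) * ct) / b
        rho = np.sqrt(u * u + v * v)
        body = np.clip(0.35 + 0.65 * np.clip(1.0 - rho**2, 0.0, 1.0), 0.0, 1.0)
        w = edge_px / min(a, b)
        falloff = np.clip((1.0 + w - rho) / w, 0.0, 1.0)
        profile = np.maximum(profile, body * falloff)
        mask |= rho <= 1.0
    return profile, mask


def generate_phantom(spec: PhantomSpec) -> tuple[MedicalImage, BinaryMask]:
    """Deterministic phantom + exact ground-truth mask for a seed.

    The frame spans the full dynamic range (background contains true zeros,
    the brightest blob pixel equals ``2**bit_depth - 1``); blob interiors
    stay above ~0.3 of the range, modulated by smooth seeded texture.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    peak = (1 << spec.bit_depth) - 1

    lo_t, hi_t = spec.target_foreground
    base_axis = 0.16 * min(rows, cols) / np.sqrt(spec.n_blobs) * np.sqrt(
        (lo_t + hi_t) / 2.0 / 0.128
    )
    params = []
    for _ in range(spec.n_blobs):
        cy = rng.uniform(0.28, 0.72) * rows
        cx = rng.uniform(0.28, 0.72) * cols
        a = base_axis * rng.uniform(0.75, 1.3)
        b = base_axis * rng.uniform(0.75, 1.3)
        theta = rng.uniform(0, np.pi)
        params.append([cy, cx, a, b, theta])

    profile = mask = None
    for attempt in range(10):
        profile, mask = _blob_field(spec.shape, params, edge_px=2.5)
        frac = mask.mean()
        if frac > 0.9:
            raise RuntimeError("blobs cover more than 90% of the frame")
        if lo_t <= frac <= hi_t:
            break
        scale = np.sqrt(((lo_t + hi_t) / 2.0) / max(frac, 1e-6))
        scale = float(np.clip(scale, 0.7, 1.4))
        for p in params:
            p[2] *= scale
            p[3] *= scale
    else:
        raise RuntimeError(
            f"could not reach foreground fraction in {spec.target_foreground} "
            "after 10 attempts"
        )

    # smooth multiplicative texture on the blobs
    tex = gaussian_filter(rng.standard_normal(spec.shape), sigma=min(rows, cols) / 16)
    tex /= max(np.abs(tex).max(), 1e-12)
    textured = profile * (1.0 + 0.25 * tex)
    textured /= textured[mask].max()  # brightest blob pixel spans the full range
    textured[mask] = np.clip(textured[mask], 0.32, 1.0)

    # background: faint non-negative sensor noise, bounded and mostly near 0
    bound = spec.background_noise_level * peak * 0.01
    noise = np.abs(rng.normal(0.0, bound / 3.0, spec.shape))
    noise = np.clip(noise, 0.0, bound)

    img = textured * peak
    img[~mask] = noise[~mask]
    img = np.clip(np.round(img), 0, peak)
    return (
        MedicalImage(img.astype(np.uint16), bit_depth=spec.bit_depth,
                     modality=spec.modality_style),
        BinaryMask(mask.astype(np.uint8)),
    )


_FIRST = ["Ada", "Brahim", "Chen", "Dalia", "Emil", "Farida", "Goran", "Hana",
          "Ines", "Jonas", "Karim", "Lena", "Mounir", "Nadia", "Omar", "Priya"]
_LAST = ["Abassi", "Berger", "Cissoko", "Dahmani", "Eriksen", "Fortin", "Guellati",
         "Haddad", "Ivanov", "Jensen", "Khellef", "Lindqvist", "Mansouri", "Novak"]


def generate_patient_record(seed: int) -> str:
    """Plausible synthetic patient record; deterministic, never real PHI.

    The record id encodes the seed directly, so distinct seeds always give
    distinct records, and the default record fits the QR capacity used by
    the pipeline with room to spare.
    """
    rng = np.random.default_rng(seed)
    name = f"{_FIRST[rng.integers(len(_FIRST))]} {_LAST[rng.integers(len(_LAST))]}"
    age = int(rng.integers(18, 95))
    modality = "CT" if rng.integers(2) else "MR"
    day = int(rng.integers(1, 29))
    month = int(rng.integers(1, 13))
    return (
        f"Name: {name}; ID: MRN-{seed:07d}; Age: {age}; "
        f"Modality: {modality}; Date: 2025-{month:02d}-{day:02d}"
    )
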