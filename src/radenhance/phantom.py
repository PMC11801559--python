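"""Seeded synthetic radiograph phantoms with ground truth.

A phantom is a smooth soft-tissue-like background (sum of broad Gaussian
blobs) with bright elongated bone-like ridges on top, degraded by mild blur,
global contrast compression and additive Gaussian noise. All randomness flows
through one ``numpy.random.Generator`` (PCG64) seeded from the spec, so images
are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .raster_io import NormalizedImage, RawImage, quantize

__all__ = ["PhantomSpec", "PhantomResult", "generate_phantom", "make_fixture_batch"]


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 256
    width: int = 256
    n_ridges: int = 4
    ridge_intensity: tuple[float, float] = (0.65, 0.9)
    background_blobs: int = 6
    blob_intensity: tuple[float, float] = (0.25, 0.5)
    texture_amp: float = 0.22
    contrast_factor: float = 0.55
    offset: float = 0.15
    noise_sigma: float = 0.02
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("phantom must be at least 2x2")
        if not 0.0 < self.contrast_factor <= 1.0:
            raise ValueError("contrast_factor must be in (0, 1]")
        if self.offset < 0 or self.offset + self.contrast_factor > 1.0 + 1e-12:
            raise ValueError("offset + contrast_factor must not exceed 1")
        for low, high in (self.ridge_intensity, self.blob_intensity):
            if not 0.0 <= low <= high <= 1.0:
                raise ValueError("intensity pairs must be ordered within [0, 1]")
        if self.noise_sigma < 0 or self.blur_sigma < 0 or self.texture_amp < 0:
            raise ValueError("noise_sigma, blur_sigma and texture_amp must be non-negative")
        if self.n_ridges < 1 or self.background_blobs < 0:
            raise ValueError("need at least one ridge and >= 0 blobs")


@dataclass(frozen=True)
class PhantomResult:
    image: RawImage
    bone_mask: np.ndarray
    clean: NormalizedImage
    spec: PhantomSpec


def _segment_distance(
    yy: np.ndarray, xx: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Per-pixel Euclidean distance to the segment p0-p1."""
    d = p1 - p0
    length_sq = float(d @ d)
    if length_sq == 0.0:
        return np.hypot(yy - p0[0], xx - p0[1])
    t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / length_sq
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(yy - (p0[0] + t * d[0]), xx - (p0[1] + t * d[1]))


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build the clean phantom, its bone mask, and the degraded 8-bit image."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    background = np.zeros((h, w))
    for _ in range(spec.background_blobs):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        sy = rng.uniform(0.15, 0.45) * h
        sx = rng.uniform(0.15, 0.45) * w
        amp = rng.uniform(*spec.blob_intensity)
        background += amp * np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2) / 2)
    background = np.clip(background, 0.0, spec.blob_intensity[1])

    ridges = np.zeros((h, w))
    bone_mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_ridges):
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.4, 0.9) * min(h, w)
        p1 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
        half_width = rng.uniform(2.0, 5.0)
        intensity = rng.uniform(*spec.ridge_intensity)
        dist = _segment_distance(yy, xx, p0, p1)
        # 1-px linear falloff outside the core half-width anti-aliases edges
        profile = np.clip(half_width + 1.0 - dist, 0.0, 1.0)
        ridges = np.maximum(ridges, intensity * profile)
        bone_mask |= dist <= half_width

    clean = np.maximum(background, ridges)
    if spec.texture_amp > 0:
        # fine trabecular-like texture so the clean image carries real detail
        # contrast that blur and range compression can destroy
        tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 0.7, mode="nearest")
        tex /= max(float(np.abs(tex).max()), 1e-12)
        clean = clean + spec.texture_amp * tex
    clean = np.clip(clean, 0.0, 1.0)

    degraded = clean
    if spec.blur_sigma > 0:
        degraded = ndimage.gaussian_filter(degraded, spec.blur_sigma, mode="nearest")
    degraded = spec.offset + spec.contrast_factor * degraded
    if spec.noise_sigma > 0:
        degraded = degraded + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    pixels = quantize(np.clip(degraded, 0.0, 1.0)).astype(np.uint8)

    return PhantomResult(
        image=RawImage(pixels=pixels, bit_depth=8),
        bone_mask=bone_mask,
        clean=NormalizedImage(values=clean),
        spec=spec,
    )


def make_fixture_batch(
    n: int, base_seed: int, spec: PhantomSpec | None = None
) -> list[PhantomResult]:
    """n phantoms with seeds base_seed .. base_seed + n - 1."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    template = asdict(spec or PhantomSpec())
    results = []
    for k in range(n):
        template["seed"] = base_seed + k
        results.append(generate_phantom(PhantomSpec(**template)))
    return results
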