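"""Stage 1: contrast enhancement by tissue-attenuation decomposition.

The normalized radiograph is split into a "removable" high-attenuation
component (soft tissue / fat, estimated from windowed local extrema) and a
detail component; subtracting a data-driven fraction of the removable part and
re-stretching the dynamic range raises the contrast of bone and key tissue.

The per-pixel brightness exponent ``psi`` is constructed so that the stretch
has two algebraic anchors: pixels equal to the local maximum map to themselves,
and pixels equal to the removable component map to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .raster_io import NormalizedImage

__all__ = [
    "ContrastParams",
    "LocalExtrema",
    "AttenuationMaps",
    "compute_local_extrema",
    "removable_factor",
    "removable_component",
    "brightness_exponent",
    "apply_contrast_enhancement",
    "run_contrast_stage",
]


@dataclass(frozen=True)
class ContrastParams:
    """Free parameters of the contrast stage.

    ``window`` is the odd side length of the square neighborhood used for the
    local extrema; ``eps`` guards every quotient and logarithm;
    ``degenerate_policy`` chooses the output where the stretch denominator
    collapses (constant neighborhoods).
    """

    window: int = 15
    eps: float = 1e-6
    degenerate_policy: Literal["pass_through", "zero"] = "pass_through"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if self.degenerate_policy not in ("pass_through", "zero"):
            raise ValueError(f"unknown degenerate_policy {self.degenerate_policy!r}")


@dataclass(frozen=True)
class LocalExtrema:
    """Windowed local maximum and minimum maps of a normalized image."""

    local_max: np.ndarray
    local_min: np.ndarray


@dataclass
class AttenuationMaps:
    """Per-pixel intermediates of the contrast stage.

    beta : removable factor in (0, 1]
    removable : beta * local_min
    psi : non-negative brightness-consistency exponent
    t_variance : scalar sample variance of the local-minimum map
    """

    beta: np.ndarray | None = None
    removable: np.ndarray | None = None
    psi: np.ndarray | None = None
    t_variance: float | None = None


def compute_local_extrema(image: NormalizedImage, params: ContrastParams) -> LocalExtrema:
    """Per-pixel max/min over a window x window neighborhood, replicate-padded."""
    if params.window > min(image.height, image.width):
        warnings.warn(
            f"window {params.window} exceeds image extent {image.shape}; "
            "extrema degenerate toward global extrema",
            stacklevel=2,
        )
    v = image.values
    local_max = ndimage.maximum_filter(v, size=params.window, mode="nearest")
    local_min = ndimage.minimum_filter(v, size=params.window, mode="nearest")
    return LocalExtrema(local_max=local_max, local_min=local_min)


def removable_factor(extrema: LocalExtrema, params: ContrastParams) -> AttenuationMaps:
    """beta = exp(-local_max * var(local_min) / local_min), eps-guarded below.

    The variance is the single scalar sample variance (n-1 denominator) of the
    whole local-minimum map, not a windowed quantity.
    """
    t_var = float(np.var(extrema.local_min, ddof=1))
    denom = np.maximum(extrema.local_min, params.eps)
    beta = np.exp(-extrema.local_max * t_var / denom)
    return AttenuationMaps(beta=beta, t_variance=t_var)


def removable_component(maps: AttenuationMaps, extrema: LocalExtrema) -> AttenuationMaps:
    """removable = beta * local_min."""
    if maps.beta is None:
        raise ValueError("beta not populated; call removable_factor first")
    maps.removable = maps.beta * extrema.local_min
    return maps


def brightness_exponent(
    maps: AttenuationMaps, extrema: LocalExtrema, params: ContrastParams
) -> AttenuationMaps:
    """psi = ln(1 - removable*(1/local_max - 1)) / ln(local_max).

    Where the local maximum is (numerically) 1 the exponent is irrelevant to
    the stretch and is set to 1 by convention; the log argument is clamped to
    [eps, 1] so psi stays finite and non-negative.
    """
    if maps.removable is None:
        raise ValueError("removable not populated; call removable_component first")
    eps = params.eps
    g = extrema.local_max
    at_one = g >= 1.0 - eps
    g_safe = np.where(at_one, 0.5, np.maximum(g, eps))
    arg = 1.0 - maps.removable * (1.0 / g_safe - 1.0)
    arg = np.clip(arg, eps, 1.0)
    psi = np.log(arg) / np.log(g_safe)
    maps.psi = np.where(at_one, 1.0, psi)
    return maps


def apply_contrast_enhancement(
    image: NormalizedImage,
    extrema: LocalExtrema,
    maps: AttenuationMaps,
    params: ContrastParams,
) -> NormalizedImage:
    """E = (I - removable) / (local_max**psi - removable), clamped to [0, 1].

    Degenerate pixels (denominator below eps) follow ``degenerate_policy``.
    """
    if maps.removable is None or maps.psi is None:
        raise ValueError("maps not fully populated; run the preceding steps")
    numer = np.maximum(image.values - maps.removable, 0.0)
    with np.errstate(invalid="ignore"):
        stretched = np.power(np.maximum(extrema.local_max, 0.0), maps.psi)
    denom = stretched - maps.removable
    degenerate = denom < params.eps
    enhanced = numer / np.maximum(denom, params.eps)
    fallback = image.values if params.degenerate_policy == "pass_through" else 0.0
    enhanced = np.where(degenerate, fallback, enhanced)
    return NormalizedImage(values=np.clip(enhanced, 0.0, 1.0))


def run_contrast_stage(
    image: NormalizedImage, params: ContrastParams | None = None
) -> tuple[NormalizedImage, LocalExtrema, AttenuationMaps]:
    """Full stage 1: extrema -> beta -> removable -> psi -> stretched image."""
    params = params or ContrastParams()
    extrema = compute_local_extrema(image, params)
    maps = removable_factor(extrema, params)
    maps = removable_component(maps, extrema)
    maps = brightness_exponent(maps, extrema, params)
    enhanced = apply_contrast_enhancement(image, extrema, maps, params)
    return enhanced, extrema, maps
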