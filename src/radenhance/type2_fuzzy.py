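"""Stage 2: sharpness enhancement with interval type-II fuzzy memberships.

Intensities are fuzzified by a min-max stretch, an interval membership
[lower, upper] is built per pixel from global image statistics, the interval is
collapsed with a Hamacher t-conorm whose parameter is the global variance, and
the result is gamma-corrected with its maximum preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .raster_io import NormalizedImage

__all__ = [
    "SharpnessParams",
    "GlobalStats",
    "MembershipMaps",
    "fuzzify",
    "global_stats",
    "upper_membership",
    "lower_membership",
    "hamacher_tconorm",
    "gamma_correction",
    "run_sharpness_stage",
]


@dataclass(frozen=True)
class SharpnessParams:
    """alpha: enhancement strength in (0,1); gamma: power-law exponent > 0."""

    alpha: float = 0.7
    gamma: float = 1.2
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")


@dataclass(frozen=True)
class GlobalStats:
    """Global mean and sample standard deviation (n-1 denominator)."""

    mu: float
    sigma: float
    n: int


@dataclass
class MembershipMaps:
    """upper/lower interval bounds, fused t-conorm map, and final output."""

    upper: np.ndarray | None = None
    lower: np.ndarray | None = None
    tconorm: np.ndarray | None = None
    output: np.ndarray | None = None
    degenerate: bool = False


FuzzyInput = Union[NormalizedImage, np.ndarray]


def _vals(image: FuzzyInput) -> np.ndarray:
    if isinstance(image, NormalizedImage):
        return image.values
    return np.asarray(image, dtype=np.float64)


def fuzzify(image: FuzzyInput) -> tuple[np.ndarray, bool]:
    """Min-max stretch onto [0, 1].

    Returns ``(stretched, degenerate)``; a constant input yields all zeros with
    the degenerate flag set.
    """
    v = _vals(image)
    lo, hi = float(v.min()), float(v.max())
    if hi - lo == 0.0:
        return np.zeros_like(v), True
    return (v - lo) / (hi - lo), False


def global_stats(f: FuzzyInput) -> GlobalStats:
    v = _vals(f)
    if v.size < 2:
        raise ValueError(f"need at least 2 pixels for sample statistics, got {v.size}")
    return GlobalStats(mu=float(v.mean()), sigma=float(v.std(ddof=1)), n=v.size)


def upper_membership(
    f: FuzzyInput, stats: GlobalStats, params: SharpnessParams
) -> np.ndarray:
    """u = f**alpha + (1 - f**alpha) * sigma**(2*alpha); u in [sigma**(2a), 1]."""
    fa = np.power(_vals(f), params.alpha)
    return fa + (1.0 - fa) * stats.sigma ** (2.0 * params.alpha)


def lower_membership(
    f: FuzzyInput,
    stats: GlobalStats,
    params: SharpnessParams,
    upper: np.ndarray | None = None,
) -> np.ndarray:
    """w = (alpha*mu/(sigma+alpha)) * (f - alpha*mu), clamped into [0, upper].

    The raw linear stretch around the anchor alpha*mu can leave [0, u];
    interval semantics require lower <= upper, so the clamp is applied here.
    """
    anchor = params.alpha * stats.mu
    scale = anchor / (stats.sigma + params.alpha)
    raw = scale * (_vals(f) - anchor)
    hi = upper if upper is not None else 1.0
    return np.clip(raw, 0.0, hi)


def hamacher_tconorm(
    upper: np.ndarray | float,
    lower: np.ndarray | float,
    sigma_sq: float,
    eps: float = 1e-6,
) -> np.ndarray:
    """Parametric Hamacher sum S(u, w) with parameter sigma_sq.

    S = (u + w + (sigma_sq - 2) * u * w) / (1 - (1 - sigma_sq) * u * w);
    degenerate denominators (< eps, reached only as u*w -> 1) give 1.
    """
    u = np.asarray(upper, dtype=np.float64)
    w = np.asarray(lower, dtype=np.float64)
    uw = u * w
    numer = u + w + (sigma_sq - 2.0) * uw
    denom = 1.0 - (1.0 - sigma_sq) * uw
    out = np.where(denom < eps, 1.0, numer / np.where(denom < eps, 1.0, denom))
    return np.clip(out, 0.0, 1.0)


def gamma_correction(t: np.ndarray, params: SharpnessParams) -> np.ndarray:
    """L = max(t) * (t / max(t))**gamma; exact max preservation, monotone in t."""
    peak = float(np.max(t))
    if peak == 0.0:
        return np.zeros_like(t)
    return peak * np.power(t / peak, params.gamma)


def run_sharpness_stage(
    image: NormalizedImage, params: SharpnessParams | None = None
) -> tuple[NormalizedImage, GlobalStats, MembershipMaps]:
    """Full stage 2: fuzzify -> stats -> interval bounds -> t-conorm -> gamma.

    Constant inputs are returned unchanged with the degenerate flag set.
    """
    params = params or SharpnessParams()
    f, degenerate = fuzzify(image)
    if degenerate:
        maps = MembershipMaps(degenerate=True, output=image.values.copy())
        stats = GlobalStats(mu=float(image.values.mean()), sigma=0.0, n=image.values.size)
        return image, stats, maps
    stats = global_stats(f)
    upper = upper_membership(f, stats, params)
    lower = lower_membership(f, stats, params, upper=upper)
    tmap = hamacher_tconorm(upper, lower, stats.sigma**2, eps=params.eps)
    out = gamma_correction(tmap, params)
    maps = MembershipMaps(upper=upper, lower=lower, tconorm=tmap, output=out)
    return NormalizedImage(values=np.clip(out, 0.0, 1.0)), stats, maps
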