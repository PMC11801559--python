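"""No-reference image quality metrics and a pluggable metric registry.

Two formula-based metrics are built in: Average Gradient (AG), a detail
contrast proxy computed on the 0-255 intensity scale, and Information Entropy
(IE), the Shannon entropy in bits of the 256-bin gray-level histogram.
Learned metrics (e.g. regression-based quality models) are not re-implemented;
external callables can be registered and show up as extra score columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .raster_io import DimensionError, ImageLike, as_octet_array, quantize

__all__ = [
    "QualityScores",
    "MetricRegistry",
    "average_gradient",
    "information_entropy",
    "score_image",
    "compare_methods",
]

logger = logging.getLogger(__name__)

MetricFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class QualityScores:
    ag: float
    ie: float
    extras: dict[str, float | None] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {"ag": self.ag, "ie": self.ie, **self.extras}


class MetricRegistry:
    """name -> callable mapping for external no-reference metrics.

    Callables receive the image as a float array on the 0-255 scale and must
    return a float. Failures are logged and recorded as missing scores rather
    than aborting a batch.
    """

    def __init__(self) -> None:
        self._metrics: dict[str, MetricFn] = {}

    def register(self, name: str, fn: MetricFn) -> None:
        self._metrics[name] = fn

    def names(self) -> list[str]:
        return list(self._metrics)

    def run_all(self, octet: np.ndarray) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for name, fn in self._metrics.items():
            try:
                out[name] = float(fn(octet))
            except Exception:
                logger.warning("external metric %r failed; recording as missing", name)
                out[name] = None
        return out


def average_gradient(image: ImageLike | np.ndarray) -> float:
    """Mean magnitude of forward differences over the (M-1)x(N-1) interior.

    AG = mean over interior of sqrt((dx**2 + dy**2) / 2), with dx and dy the
    horizontal and vertical forward differences on the 0-255 scale.
    """
    arr = _to_octet(image)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DimensionError("average gradient needs at least a 2x2 image")
    dx = arr[:-1, 1:] - arr[:-1, :-1]
    dy = arr[1:, :-1] - arr[:-1, :-1]
    return float(np.mean(np.sqrt((dx**2 + dy**2) / 2.0)))


def information_entropy(image: ImageLike | np.ndarray) -> float:
    """Shannon entropy in bits of the 256-bin histogram (0*log0 := 0)."""
    arr = _to_octet(image)
    levels = quantize(np.clip(arr, 0.0, 255.0) / 255.0)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _to_octet(image: ImageLike | np.ndarray) -> np.ndarray:
    if isinstance(image, np.ndarray):
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim != 2:
            raise DimensionError(f"expected 2-D array, got ndim={arr.ndim}")
        if arr.size and arr.max() <= 1.0:
            arr = arr * 255.0
        return arr
    return as_octet_array(image)


def score_image(image: ImageLike, registry: MetricRegistry | None = None) -> QualityScores:
    """Compute AG and IE, plus any registered external metrics."""
    octet = _to_octet(image)
    extras = registry.run_all(octet) if registry is not None else {}
    return QualityScores(
        ag=average_gradient(image), ie=information_entropy(image), extras=extras
    )


def compare_methods(
    images: dict[str, ImageLike], registry: MetricRegistry | None = None
) -> pd.DataFrame:
    """Score a named collection of renderings of the same source radiograph.

    Returns a table with one row per metric, one column per method name, and a
    trailing per-metric ``mean`` column.
    """
    if not images:
        raise DimensionError("compare_methods needs at least one image")
    columns: dict[str, dict[str, float]] = {}
    for name, image in images.items():
        scores = score_image(image, registry).as_dict()
        columns[name] = {k: (math.nan if v is None else v) for k, v in scores.items()}
    table = pd.DataFrame(columns)
    table["mean"] = table.mean(axis=1)
    table.index.name = "metric"
    return table
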