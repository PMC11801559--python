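"""Orchestration: two-stage enhancement, ablation modes, and batch reports.

Modes mirror the ablation study design: ``full`` chains both stages,
``no_rem`` drops the fuzzy sharpening (contrast stage only), ``no_cem`` drops
the contrast stage (sharpening applied directly to the normalized input).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from . import __version__
from .nr_metrics import MetricRegistry, score_image
from .raster_io import (
    DegenerateImageError,
    NormalizedImage,
    RawImage,
    normalize,
    read_image,
    to_octet,
    write_image,
)
from .tissue_attenuation import (
    AttenuationMaps,
    ContrastParams,
    LocalExtrema,
    run_contrast_stage,
)
from .type2_fuzzy import GlobalStats, MembershipMaps, SharpnessParams, run_sharpness_stage

__all__ = [
    "Mode",
    "EnhancementConfig",
    "EnhancementResult",
    "BatchReport",
    "MODES",
    "enhance",
    "run_batch",
    "run_ablation",
]

logger = logging.getLogger(__name__)

Mode = Literal["full", "no_rem", "no_cem"]
MODES: tuple[Mode, ...] = ("full", "no_rem", "no_cem")

REPORT_COLUMNS = (
    "path,mode,alpha,gamma,window,ag_before,ag_after,ie_before,ie_after"
)


@dataclass(frozen=True)
class EnhancementConfig:
    contrast: ContrastParams = field(default_factory=ContrastParams)
    sharpness: SharpnessParams = field(default_factory=SharpnessParams)
    mode: Mode = "full"
    norm_by_depth: bool = False
    dump_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def metadata(self) -> dict:
        return {
            "version": __version__,
            "mode": self.mode,
            "alpha": self.sharpness.alpha,
            "gamma": self.sharpness.gamma,
            "window": self.contrast.window,
            "eps": self.contrast.eps,
            "norm_by_depth": self.norm_by_depth,
        }


@dataclass
class EnhancementResult:
    output: RawImage
    enhanced: NormalizedImage
    normalized: NormalizedImage
    contrast_output: NormalizedImage | None = None
    extrema: LocalExtrema | None = None
    attenuation: AttenuationMaps | None = None
    stats: GlobalStats | None = None
    membership: MembershipMaps | None = None


@dataclass
class BatchReport:
    rows: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        """Per-metric means over all rows (the averaged-table analogue)."""
        out: dict[str, float] = {}
        if not self.rows:
            return out
        for key in ("ag_before", "ag_after", "ie_before", "ie_after"):
            out[key] = sum(r[key] for r in self.rows) / len(self.rows)
        return out

    def per_mode_summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for mode in MODES:
            rows = [r for r in self.rows if r["mode"] == mode]
            if rows:
                out[mode] = {
                    key: sum(r[key] for r in rows) / len(rows)
                    for key in ("ag_after", "ie_after")
                }
        return out

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        lines = [REPORT_COLUMNS]
        for r in self.rows:
            lines.append(
                f"{r['path']},{r['mode']},{r['alpha']!r},{r['gamma']!r},"
                f"{r['window']},{r['ag_before']!r},{r['ag_after']!r},"
                f"{r['ie_before']!r},{r['ie_after']!r}"
            )
        path.write_text("\n".join(lines) + "\n")


def enhance(image: RawImage, config: EnhancementConfig | None = None) -> EnhancementResult:
    """Run the configured enhancement mode on one raw image.

    Degenerate (constant) inputs pass through unchanged with a warning rather
    than raising, so batches survive pathological files.
    """
    config = config or EnhancementConfig()
    try:
        normalized = normalize(image, by_depth=config.norm_by_depth)
    except DegenerateImageError:
        logger.warning("all-zero image; passing through unchanged")
        zero = NormalizedImage(values=image.pixels.astype(float) * 0.0)
        return EnhancementResult(output=to_octet(zero), enhanced=zero, normalized=zero)

    result = EnhancementResult(
        output=image, enhanced=normalized, normalized=normalized
    )
    current = normalized
    if config.mode in ("full", "no_rem"):
        current, result.extrema, result.attenuation = run_contrast_stage(
            current, config.contrast
        )
        result.contrast_output = current
    if config.mode in ("full", "no_cem"):
        current, result.stats, result.membership = run_sharpness_stage(
            current, config.sharpness
        )
        if result.membership.degenerate:
            logger.warning("constant image at sharpening stage; passed through")
    result.enhanced = current
    result.output = to_octet(current)
    return result


def _dump_intermediates(result: EnhancementResult, stem: Path) -> None:
    import numpy as np

    from .raster_io import quantize

    def save16(name: str, values) -> None:
        arr = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
        px = quantize(arr, levels=65536).astype(np.uint16)
        write_image(RawImage(pixels=px, bit_depth=16), stem.parent / f"{stem.name}.{name}.tiff")

    save16("normalized", result.normalized.values)
    if result.extrema is not None:
        save16("local_max", result.extrema.local_max)
        save16("local_min", result.extrema.local_min)
    if result.attenuation is not None and result.attenuation.removable is not None:
        save16("removable", result.attenuation.removable)
    if result.contrast_output is not None:
        save16("contrast", result.contrast_output.values)
    if result.membership is not None and result.membership.tconorm is not None:
        save16("tconorm", result.membership.tconorm)


def _process_one(
    path: Path,
    config: EnhancementConfig,
    out_dir: Path,
    registry: MetricRegistry | None,
    suffix: str,
) -> dict:
    image = read_image(path)
    before = score_image(image, registry)
    result = enhance(image, config)
    after = score_image(result.output, registry)

    out_path = out_dir / f"{path.stem}{suffix}.png"
    write_image(result.output, out_path)
    sidecar = dict(config.metadata(), source=str(path))
    (out_dir / f"{path.stem}{suffix}.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    if config.dump_intermediates:
        _dump_intermediates(result, out_dir / f"{path.stem}{suffix}")

    return {
        "path": str(path),
        "mode": config.mode,
        "alpha": config.sharpness.alpha,
        "gamma": config.sharpness.gamma,
        "window": config.contrast.window,
        "ag_before": before.ag,
        "ag_after": after.ag,
        "ie_before": before.ie,
        "ie_after": after.ie,
    }


def run_batch(
    paths: Iterable[str | Path],
    config: EnhancementConfig | None = None,
    out_dir: str | Path = "enhanced",
    registry: MetricRegistry | None = None,
) -> BatchReport:
    """Enhance each image in the configured mode; failures are logged, not fatal."""
    config = config or EnhancementConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = BatchReport()
    for path in paths:
        path = Path(path)
        try:
            report.rows.append(_process_one(path, config, out_dir, registry, ""))
        except Exception as exc:
            logger.warning("failed to process %s: %s", path, exc)
            report.failures.append({"path": str(path), "error": str(exc)})
    return report


def run_ablation(
    paths: Iterable[str | Path],
    config: EnhancementConfig | None = None,
    out_dir: str | Path = "ablation",
    registry: MetricRegistry | None = None,
) -> BatchReport:
    """Run all three modes on every image (ablation-study layout)."""
    config = config or EnhancementConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = BatchReport()
    paths = [Path(p) for p in paths]
    for mode in MODES:
        mode_config = EnhancementConfig(
            contrast=config.contrast,
            sharpness=config.sharpness,
            mode=mode,
            norm_by_depth=config.norm_by_depth,
            dump_intermediates=config.dump_intermediates,
        )
        for path in paths:
            try:
                report.rows.append(
                    _process_one(path, mode_config, out_dir, registry, f".{mode}")
                )
            except Exception as exc:
                logger.warning("failed to process %s (%s): %s", path, mode, exc)
                report.failures.append(
                    {"path": str(path), "mode": mode, "error": str(exc)}
                )
    return report
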