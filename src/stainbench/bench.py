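"""End-to-end benchmark orchestration.

Reproduces the comparative-analysis shape: select the reference image from
a panel by the R/B-ratio rule, normalize every other image with every
requested method (whole-image, never patchwise), score each result with
the metric suite, and aggregate to per-method mean/std tables plus the
red/blue-ratio convergence diagnostic.

Normalization methods are looked up in a plug-in registry so third-party
normalizers can be benchmarked without core changes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from matplotlib.figure import Figure

from . import __version__
from .color import DEFAULT_I0, read_image
from .exceptions import InvalidImageError, StainBenchError
from .metrics import (
    MetricConfig,
    MetricRecord,
    RandomProjectionExtractor,
    evaluate_sample,
    lab_channel_ranges,
)
from .normalize import (
    NormalizationResult,
    histogram_match,
    macenko_normalize,
    reinhard,
    vahadane_normalize,
)
from .select import rb_ratio, select_reference

__all__ = [
    "TileSet",
    "BenchConfig",
    "BenchmarkReport",
    "METHODS",
    "register_method",
    "tile_image",
    "load_panel",
    "run_benchmark",
    "write_report",
]

#: Metrics where larger is better; the rest are minimized.
_MAXIMIZE = {"intersection", "pcc", "ssim"}
_METRICS = list(MetricRecord.METRIC_FIELDS)


@dataclass
class TileSet:
    """Row-major non-overlapping grid of tiles cut from one image."""

    tiles: list[np.ndarray]
    origins: list[tuple[int, int]]
    tile_size: int


def tile_image(img: np.ndarray, tile_size: int) -> TileSet:
    """Cut an image into a deterministic non-overlapping grid.

    Right/bottom remainders smaller than ``tile_size`` are dropped rather
    than padded, so tile statistics are never diluted by artificial
    borders.  An image smaller than one tile yields an empty TileSet with
    a warning.
    """
    if tile_size < 32:
        raise InvalidImageError("tile_size must be at least 32")
    arr = np.asarray(img)
    h, w = arr.shape[:2]
    tiles: list[np.ndarray] = []
    origins: list[tuple[int, int]] = []
    if h < tile_size or w < tile_size:
        warnings.warn(
            f"image {h}x{w} is smaller than one {tile_size}px tile; "
            "returning an empty tile set",
            stacklevel=2,
        )
        return TileSet(tiles, origins, tile_size)
    for row in range(0, h - tile_size + 1, tile_size):
        for col in range(0, w - tile_size + 1, tile_size):
            tiles.append(arr[row : row + tile_size, col : col + tile_size])
            origins.append((row, col))
    return TileSet(tiles, origins, tile_size)


@dataclass
class BenchConfig:
    """All benchmark, method and metric parameters in one place."""

    methods: tuple[str, ...] = ("histmatch", "reinhard", "macenko", "vahadane")
    tile_size: int = 128
    bins: int = 256
    ssim_window: int = 11
    seed: int = 17
    include_reference: bool = False
    od_threshold: float = 0.15
    angle_percentile: float = 1.0
    scale_percentile: float = 99.0
    sparsity: float = 0.1
    n_iter: int = 200
    mask_od: float | None = None
    i0: float = DEFAULT_I0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        d["methods"] = list(self.methods)
        return d


# ---------------------------------------------------------------------------
# Method registry
# ---------------------------------------------------------------------------

MethodFn = Callable[[np.ndarray, np.ndarray, BenchConfig], NormalizationResult]

METHODS: dict[str, MethodFn] = {}


def register_method(name: str, fn: MethodFn) -> None:
    """Add a normalization method to the benchmark registry."""
    METHODS[name] = fn


register_method("histmatch", lambda s, r, cfg: histogram_match(s, r))
register_method("reinhard", lambda s, r, cfg: reinhard(s, r))
register_method(
    "macenko",
    lambda s, r, cfg: macenko_normalize(
        s, r, cfg.od_threshold, cfg.angle_percentile, cfg.scale_percentile, cfg.i0
    ),
)
register_method(
    "vahadane",
    lambda s, r, cfg: vahadane_normalize(
        s, r, cfg.sparsity, cfg.n_iter, cfg.scale_percentile, cfg.od_threshold, cfg.i0
    ),
)


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Per-sample metric records plus aggregates and R/B diagnostics."""

    records: list[MetricRecord]
    errors: list[dict[str, str]]
    aggregates: pd.DataFrame
    rb_before: dict[str, float]
    rb_after: dict[str, dict[str, float]]
    reference_id: str
    config: BenchConfig
    metadata: dict[str, Any] = field(default_factory=dict)


def load_panel(panel_dir: str | Path) -> tuple[list[str], list[np.ndarray]]:
    """Load all PNG/TIFF images in a directory, sorted by filename."""
    paths = sorted(
        p
        for p in Path(panel_dir).iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not paths:
        raise InvalidImageError(f"no PNG/TIFF images found in {panel_dir}")
    return [p.stem for p in paths], [read_image(p) for p in paths]


def _as_panel(panel) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(panel, (str, Path)):
        return load_panel(panel)
    if isinstance(panel, Mapping):
        ids = list(panel.keys())
        return ids, [panel[i] for i in ids]
    ids_images = list(panel)
    return [f"{i:02d}" for i in range(len(ids_images))], ids_images


def _aggregate(records: Sequence[MetricRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.as_dict() for r in records])
    if df.empty:
        return pd.DataFrame()
    return df.groupby("method")[_METRICS].agg(["mean", "std"])


def run_benchmark(
    panel,
    methods: Sequence[str] | None = None,
    config: BenchConfig | None = None,
) -> BenchmarkReport:
    """Run the full pipeline on a panel.

    ``panel`` may be a directory of rasters, a mapping id -> image, or a
    sequence of images.  The reference is selected by the R/B rule and by
    default excluded from the aggregates (set
    ``config.include_reference=True`` to score the self-normalization of
    the reference as well).  A method failure on one sample is recorded as
    an error entry, never a crash.
    """
    if config is None:
        config = BenchConfig()
    if methods is None:
        methods = config.methods
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise StainBenchError(f"unknown methods: {unknown}")
    ids, images = _as_panel(panel)
    if len(images) < 2:
        raise InvalidImageError("benchmark needs a panel of at least 2 images")

    ref_idx, ratios = select_reference(images, ids)
    reference = images[ref_idx]
    reference_id = ids[ref_idx]
    rb_before = {r.sample_id: r.ratio for r in ratios}

    metric_cfg = MetricConfig(
        bins=config.bins,
        ranges=lab_channel_ranges(images),
        tile_size=config.tile_size,
        ssim_window=config.ssim_window,
        extractor=RandomProjectionExtractor(seed=config.seed),
        mask_od=config.mask_od,
        i0=config.i0,
    )

    records: list[MetricRecord] = []
    errors: list[dict[str, str]] = []
    rb_after: dict[str, dict[str, float]] = {m: {} for m in methods}
    for sid, img in zip(ids, images):
        if sid == reference_id and not config.include_reference:
            continue
        for method in methods:
            try:
                result = METHODS[method](img, reference, config)
                rb_after[method][sid] = rb_ratio(result.image)
                records.append(
                    evaluate_sample(
                        img, result.image, reference, metric_cfg, sid, method
                    )
                )
            except StainBenchError as exc:
                errors.append({"sample_id": sid, "method": method, "error": str(exc)})

    return BenchmarkReport(
        records=records,
        errors=errors,
        aggregates=_aggregate(records),
        rb_before=rb_before,
        rb_after=rb_after,
        reference_id=reference_id,
        config=config,
        metadata={
            "version": __version__,
            "n_samples": len(images),
            "include_reference": config.include_reference,
        },
    )


def write_report(report: BenchmarkReport, out_dir: str | Path) -> dict[str, Path]:
    """Write CSV tables, the R/B convergence plot and run metadata.

    ``records.csv`` holds one row per sample x method; ``aggregates.csv``
    one row per method with mean/std per metric and a ``best_<metric>``
    flag (max for intersection/pcc/ssim, min for euclidean/js/fid).
    Reruns with the same seed produce byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rec_df = pd.DataFrame([r.as_dict() for r in report.records])
    if not rec_df.empty:
        rec_df = rec_df.sort_values(["method", "sample_id"]).reset_index(drop=True)
    paths["records"] = out / "records.csv"
    rec_df.to_csv(paths["records"], index=False)

    agg = report.aggregates
    flat = pd.DataFrame(index=agg.index)
    for metric in _METRICS:
        if (metric, "mean") not in agg.columns:
            continue
        flat[f"{metric}_mean"] = agg[(metric, "mean")]
        flat[f"{metric}_std"] = agg[(metric, "std")]
        means = agg[(metric, "mean")]
        best = means.idxmax() if metric in _MAXIMIZE else means.idxmin()
        flat[f"best_{metric}"] = flat.index == best
    paths["aggregates"] = out / "aggregates.csv"
    flat.to_csv(paths["aggregates"])

    if report.errors:
        paths["errors"] = out / "errors.csv"
        pd.DataFrame(report.errors).to_csv(paths["errors"], index=False)

    paths["rb_plot"] = out / "rb_ratio.png"
    _plot_rb(report, paths["rb_plot"])

    meta = {
        "config": report.config.to_dict(),
        "reference_id": report.reference_id,
        "rb_before": report.rb_before,
        "rb_after": report.rb_after,
        **report.metadata,
    }
    paths["metadata"] = out / "run.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=float)
    return paths


def _plot_rb(report: BenchmarkReport, path: Path) -> None:
    fig = Figure(figsize=(8, 4.5))
    ax = fig.add_subplot(111)
    ids = sorted(report.rb_before)
    x = np.arange(len(ids))
    ax.scatter(
        x, [report.rb_before[i] for i in ids], marker="o", label="original", zorder=3
    )
    for method, after in report.rb_after.items():
        pts = [(i, after[s]) for i, s in enumerate(ids) if s in after]
        if pts:
            xs, ys = zip(*pts)
            ax.scatter(xs, ys, marker=".", label=method, alpha=0.7)
    ax.axhline(1.0, linestyle=":", color="gray", label="balanced")
    ax.set_xlabel("sample")
    ax.set_ylabel("R/B mean-intensity ratio")
    ax.set_title(f"R/B convergence (reference: {report.reference_id})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
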