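"""Quantitative evaluation suite.

Color-transfer quality is scored on per-channel lαβ histograms (histogram
intersection, Pearson correlation, Euclidean distance, Jensen-Shannon
divergence, each averaged over the three channels); structural
preservation is scored with SSIM against the *original* image; and
style-plus-structure similarity is scored with a Fréchet distance between
Gaussian fits of tile-level feature clouds.

The Fréchet metric's feature extractor is pluggable.  The default is a
self-contained seeded extractor (fixed random convolution kernels plus
channel statistics) so that results are deterministic and need no network
weights; its absolute magnitudes are comparable within a run, not across
extractors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np
import scipy.linalg
from scipy.signal import fftconvolve
from skimage.metrics import structural_similarity

from .color import DEFAULT_I0, rgb_to_lab, rgb_to_od
from .exceptions import (
    BinningMismatchError,
    ExtractorMismatchError,
    InvalidImageError,
    UndefinedCorrelationError,
)

__all__ = [
    "ChannelHistogramSet",
    "FeatureCloud",
    "MetricRecord",
    "MetricConfig",
    "lab_channel_ranges",
    "lab_histograms",
    "hist_intersection",
    "hist_pcc",
    "hist_euclidean",
    "js_divergence",
    "ssim",
    "RandomProjectionExtractor",
    "extract_features",
    "frechet_distance",
    "evaluate_sample",
]

DEFAULT_BINS = 256


@dataclass(frozen=True)
class ChannelHistogramSet:
    """Three normalized histograms (l, α, β) with their shared bin edges."""

    hists: np.ndarray  # 3 x bins
    edges: np.ndarray  # 3 x (bins + 1)

    def __post_init__(self) -> None:
        hists = np.asarray(self.hists, dtype=np.float64)
        edges = np.asarray(self.edges, dtype=np.float64)
        if hists.ndim != 2 or hists.shape[0] != 3:
            raise BinningMismatchError(f"hists must be 3 x bins, got {hists.shape}")
        if edges.shape != (3, hists.shape[1] + 1):
            raise BinningMismatchError(
                f"edges shape {edges.shape} inconsistent with {hists.shape}"
            )
        if hists.min() < 0:
            raise BinningMismatchError("histogram entries must be nonnegative")
        sums = hists.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise BinningMismatchError(f"each histogram must sum to 1, got {sums}")
        object.__setattr__(self, "hists", hists)
        object.__setattr__(self, "edges", edges)


def lab_channel_ranges(images: Sequence[np.ndarray]) -> np.ndarray:
    """Global (min, max) per lαβ channel across a panel of RGB images."""
    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for img in images:
        lab = rgb_to_lab(img)
        lo = np.minimum(lo, lab.min(axis=(0, 1)))
        hi = np.maximum(hi, lab.max(axis=(0, 1)))
    return np.stack([lo, hi], axis=1)


def lab_histograms(
    img: np.ndarray,
    bins: int = DEFAULT_BINS,
    ranges: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> ChannelHistogramSet:
    """Normalized per-channel lαβ histograms of an RGB image.

    ``ranges`` fixes the bin edges (3 x 2 array of per-channel lo/hi) so
    that histograms from different images are comparable; when omitted the
    image's own channel extrema are used.  An optional boolean ``mask``
    restricts the pixels counted.
    """
    if bins < 2:
        raise BinningMismatchError("bins must be >= 2")
    lab = rgb_to_lab(img)
    if mask is not None:
        lab = lab[np.asarray(mask, bool)]
    else:
        lab = lab.reshape(-1, 3)
    if ranges is None:
        ranges = np.stack([lab.min(axis=0), lab.max(axis=0)], axis=1)
    ranges = np.asarray(ranges, dtype=np.float64)
    hists = np.empty((3, bins))
    edges = np.empty((3, bins + 1))
    for ch in range(3):
        lo, hi = ranges[ch]
        if hi - lo < 1e-12:  # constant channel: widen so all mass lands in one bin
            lo, hi = lo - 0.5, hi + 0.5
        counts, e = np.histogram(lab[:, ch], bins=bins, range=(lo, hi))
        total = counts.sum()
        hists[ch] = counts / total if total > 0 else 0.0
        if total == 0:
            hists[ch, 0] = 1.0  # degenerate: everything out of range
        edges[ch] = e
    return ChannelHistogramSet(hists, edges)


def _check_binning(a: ChannelHistogramSet, b: ChannelHistogramSet) -> None:
    if a.hists.shape != b.hists.shape or not np.allclose(a.edges, b.edges):
        raise BinningMismatchError("histogram sets use different bin edges")


def hist_intersection(a: ChannelHistogramSet, b: ChannelHistogramSet) -> float:
    """Mean over channels of the histogram intersection sum(min(a_i, b_i))."""
    _check_binning(a, b)
    return float(np.minimum(a.hists, b.hists).sum(axis=1).mean())


def hist_pcc(a: ChannelHistogramSet, b: ChannelHistogramSet) -> float:
    """Mean over channels of the Pearson correlation of bin counts."""
    _check_binning(a, b)
    vals = []
    for ch in range(3):
        x, y = a.hists[ch], b.hists[ch]
        if x.std() == 0.0 or y.std() == 0.0:
            raise UndefinedCorrelationError(
                f"channel {'lab'[ch]} histogram has zero variance"
            )
        vals.append(np.corrcoef(x, y)[0, 1])
    return float(np.mean(vals))


def hist_euclidean(a: ChannelHistogramSet, b: ChannelHistogramSet) -> float:
    """Mean over channels of the L2 distance between histograms."""
    _check_binning(a, b)
    return float(np.linalg.norm(a.hists - b.hists, axis=1).mean())


def js_divergence(a: ChannelHistogramSet, b: ChannelHistogramSet) -> float:
    """Mean over channels of the Jensen-Shannon divergence, base-2 logs.

    ``JSD = KL(a || m)/2 + KL(b || m)/2`` with ``m = (a + b)/2``; bounded
    in [0, 1], attaining 1 on disjoint supports.
    """
    _check_binning(a, b)
    vals = []
    for ch in range(3):
        p, q = a.hists[ch], b.hists[ch]
        m = 0.5 * (p + q)
        with np.errstate(divide="ignore", invalid="ignore"):
            kl_pm = np.where(p > 0, p * np.log2(p / m), 0.0)
            kl_qm = np.where(q > 0, q * np.log2(q / m), 0.0)
        vals.append(0.5 * np.nansum(kl_pm) + 0.5 * np.nansum(kl_qm))
    return float(np.mean(vals))


def ssim(x: np.ndarray, y: np.ndarray, window: int = 11) -> float:
    """Structural similarity with Gaussian-weighted local statistics.

    Stabilizers C1 = (0.01 L)^2 and C2 = (0.03 L)^2 with L = 255; computed
    per RGB channel and averaged, mean over all window positions.
    """
    xa, ya = np.asarray(x), np.asarray(y)
    if xa.shape != ya.shape:
        raise InvalidImageError(f"size mismatch: {xa.shape} vs {ya.shape}")
    return float(
        structural_similarity(
            xa.astype(np.float64),
            ya.astype(np.float64),
            win_size=window,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=255.0,
            channel_axis=-1,
        )
    )


# ---------------------------------------------------------------------------
# Feature extraction and Fréchet distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureCloud:
    """N x D feature matrix (one row per tile) tagged with its extractor."""

    vectors: np.ndarray
    extractor_id: str

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        object.__setattr__(self, "vectors", v)


class RandomProjectionExtractor:
    """Deterministic tile featurizer: random convolutions + channel statistics.

    Each tile is reduced to a small grayscale-plus-color summary: responses
    of ``n_kernels`` fixed seeded 2-D convolution kernels (mean and std of
    each response over the tile) concatenated with per-channel means and
    stds.  Dimensionality D = 2 * n_kernels + 6.
    """

    def __init__(self, seed: int = 0, n_kernels: int = 8, kernel_size: int = 5):
        rng = np.random.default_rng(seed)
        self.kernels = rng.standard_normal((n_kernels, kernel_size, kernel_size, 3))
        self.kernels /= np.sqrt((self.kernels**2).sum(axis=(1, 2, 3), keepdims=True))
        self.extractor_id = f"randproj-n{n_kernels}-k{kernel_size}-s{seed}"

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        x = np.asarray(tile, dtype=np.float64) / 255.0
        feats = []
        for k in self.kernels:
            resp = sum(
                fftconvolve(x[..., c], k[..., c], mode="valid") for c in range(3)
            )
            feats.extend([resp.mean(), resp.std()])
        feats.extend(x.mean(axis=(0, 1)))
        feats.extend(x.std(axis=(0, 1)))
        return np.asarray(feats)


def extract_features(
    img: np.ndarray,
    tile: int = 128,
    extractor: Callable[[np.ndarray], np.ndarray] | None = None,
) -> FeatureCloud:
    """Tile an image and map each tile to a feature vector.

    Tiling follows the benchmark's deterministic row-major grid (remainders
    dropped).  The default extractor is seeded and self-contained.
    """
    from .bench import tile_image  # local import: bench depends on metrics

    if extractor is None:
        extractor = RandomProjectionExtractor()
    tiles = tile_image(img, tile).tiles
    extractor_id = getattr(extractor, "extractor_id", repr(extractor))
    if not tiles:
        return FeatureCloud(np.empty((0, 1)), extractor_id)
    vectors = np.stack([extractor(t) for t in tiles])
    return FeatureCloud(vectors, extractor_id)


def frechet_distance(a: FeatureCloud, b: FeatureCloud) -> float:
    """Fréchet distance between Gaussian fits of two feature clouds.

    ``||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^(1/2))`` with a
    symmetric matrix square root; a shrinkage term ``1e-6 * I`` is added to
    both covariances for numerical stability.  Tiny negative results from
    the square root are clamped to zero.
    """
    if a.extractor_id != b.extractor_id:
        raise ExtractorMismatchError(
            f"clouds come from different extractors: "
            f"{a.extractor_id!r} vs {b.extractor_id!r}"
        )
    if a.vectors.shape[0] < 2 or b.vectors.shape[0] < 2:
        raise InvalidImageError("need at least 2 tiles per cloud for covariance")
    mu_a, mu_b = a.vectors.mean(axis=0), b.vectors.mean(axis=0)
    d = a.vectors.shape[1]
    eye = 1e-6 * np.eye(d)
    cov_a = np.cov(a.vectors, rowvar=False).reshape(d, d) + eye
    cov_b = np.cov(b.vectors, rowvar=False).reshape(d, d) + eye
    covmean = scipy.linalg.sqrtm(cov_a @ cov_b)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    diff = mu_a - mu_b
    fid = float(diff @ diff + np.trace(cov_a + cov_b - 2.0 * covmean))
    return max(fid, 0.0)


# ---------------------------------------------------------------------------
# Per-sample evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricConfig:
    """Parameters of the evaluation suite."""

    bins: int = DEFAULT_BINS
    ranges: np.ndarray | None = None
    tile_size: int = 128
    ssim_window: int = 11
    extractor: Callable[[np.ndarray], np.ndarray] | None = None
    mask_od: float | None = None  # tissue-mask OD threshold; None = off
    i0: float = DEFAULT_I0
    compute_fid: bool = True


@dataclass
class MetricRecord:
    """One row of the benchmark table: all metric values for one sample."""

    sample_id: str
    method: str
    intersection: float
    pcc: float
    euclidean: float
    js: float
    ssim: float
    fid: float

    METRIC_FIELDS = ("intersection", "pcc", "euclidean", "js", "ssim", "fid")

    def as_dict(self) -> dict[str, Any]:
        return {
            "sample_id": self.sample_id,
            "method": self.method,
            **{m: getattr(self, m) for m in self.METRIC_FIELDS},
        }


def _image_histograms(img: np.ndarray, config: MetricConfig) -> ChannelHistogramSet:
    mask = None
    if config.mask_od is not None:
        od = rgb_to_od(img, config.i0)
        mask = od.max(axis=-1) >= config.mask_od
    return lab_histograms(img, config.bins, config.ranges, mask)


def evaluate_sample(
    original: np.ndarray,
    normalized: np.ndarray,
    reference: np.ndarray,
    config: MetricConfig | None = None,
    sample_id: str = "",
    method: str = "",
) -> MetricRecord:
    """Score one normalized image.

    Histogram metrics and the Fréchet distance compare *normalized vs
    reference* (color-transfer quality); SSIM compares *normalized vs
    original* (structural integrity).  An undefined Pearson correlation is
    reported as NaN rather than zero.
    """
    if config is None:
        config = MetricConfig()
    if config.ranges is None:
        config = MetricConfig(
            **{**config.__dict__, "ranges": lab_channel_ranges([normalized, reference])}
        )
    h_norm = _image_histograms(normalized, config)
    h_ref = _image_histograms(reference, config)
    try:
        pcc = hist_pcc(h_norm, h_ref)
    except UndefinedCorrelationError:
        pcc = float("nan")
    fid = float("nan")
    if config.compute_fid:
        extractor = config.extractor or RandomProjectionExtractor()
        cloud_n = extract_features(normalized, config.tile_size, extractor)
        cloud_r = extract_features(reference, config.tile_size, extractor)
        if cloud_n.vectors.shape[0] >= 2 and cloud_r.vectors.shape[0] >= 2:
            fid = frechet_distance(cloud_n, cloud_r)
    return MetricRecord(
        sample_id=sample_id,
        method=method,
        intersection=hist_intersection(h_norm, h_ref),
        pcc=pcc,
        euclidean=hist_euclidean(h_norm, h_ref),
        js=js_divergence(h_norm, h_ref),
        ssim=ssim(normalized, original, config.ssim_window),
        fid=fid,
    )
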