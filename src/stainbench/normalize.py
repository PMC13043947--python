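"""Classical stain-normalization methods.

All four methods map ``(source, reference) -> normalized image``:

* **Histogram matching** — per-RGB-channel monotone quantile mapping of the
  source intensity distribution onto the reference's.
* **Reinhard** — per-channel moment matching (mean/std) in Ruderman lαβ.
* **Macenko** — stain deconvolution: the two stain directions are estimated
  as extreme angles of the OD point cloud projected onto its top-2 singular
  plane; per-stain concentrations are percentile-rescaled to the
  reference's and recombined with the reference stain matrix.
* **Vahadane** — like Macenko but the stain basis and concentrations come
  from a sparse non-negative matrix factorization of the tissue OD matrix,
  which tolerates stain mixing better than the SVD-based geometry.

Every method runs on the whole image at once (never patchwise), which
avoids tiling artifacts and lets whole-slide statistics drive the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .color import DEFAULT_I0, lab_to_rgb, od_to_rgb, rgb_to_lab, rgb_to_od
from .exceptions import (
    DegenerateReferenceError,
    DegenerateSourceError,
    DegenerateStainError,
    InsufficientTissueError,
)

__all__ = [
    "StainMatrix",
    "ConcentrationMap",
    "NormalizationResult",
    "histogram_match",
    "reinhard",
    "macenko_fit",
    "stain_concentrations",
    "macenko_normalize",
    "vahadane_fit",
    "vahadane_normalize",
    "angular_error_degrees",
]

#: Minimum number of tissue pixels required for a stain fit.
MIN_TISSUE_PIXELS = 100

#: Default OD threshold below which a pixel counts as background.
DEFAULT_OD_THRESHOLD = 0.15


@dataclass(frozen=True)
class StainMatrix:
    """3 x 2 matrix of unit-norm OD stain direction vectors.

    Column 0 is hematoxylin, column 1 is eosin.  Hematoxylin absorbs red
    light more strongly than blue (which is why nuclei look blue-purple),
    so it is identified as the column with the larger red-minus-blue OD
    component; ties break toward the larger red component.
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        if w.shape != (3, 2):
            raise DegenerateStainError(f"stain matrix must be 3x2, got {w.shape}")
        if w.min() < -1e-9:
            raise DegenerateStainError("stain vectors must be nonnegative")
        norms = np.linalg.norm(w, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise DegenerateStainError(
                f"stain columns must have unit norm, got {norms}"
            )
        object.__setattr__(self, "w", w)

    @classmethod
    def from_columns(cls, a: np.ndarray, b: np.ndarray) -> "StainMatrix":
        """Build from two OD directions: clamp negatives, normalize, order H/E."""
        w = np.stack([np.asarray(a, float), np.asarray(b, float)], axis=1)
        w = np.maximum(w, 0.0)
        norms = np.linalg.norm(w, axis=0)
        if np.any(norms < 1e-12):
            raise DegenerateStainError("stain vector has zero norm")
        w = w / norms
        return cls(_order_he(w))

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.w[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.w[:, 1]


def _order_he(w: np.ndarray) -> np.ndarray:
    """Order unit columns as (hematoxylin, eosin) by the red-minus-blue rule."""
    diff = w[0] - w[2]
    if diff[0] == diff[1]:  # tie: larger red component is hematoxylin
        h = int(np.argmax(w[0]))
    else:
        h = int(np.argmax(diff))
    return w[:, [h, 1 - h]]


def angular_error_degrees(a: StainMatrix, b: StainMatrix) -> np.ndarray:
    """Per-column angle (degrees) between two stain matrices."""
    cos = np.clip(np.abs(np.sum(a.w * b.w, axis=0)), 0.0, 1.0)
    return np.degrees(np.arccos(cos))


@dataclass(frozen=True)
class ConcentrationMap:
    """Per-pixel nonnegative stain amounts with the basis they refer to."""

    c: np.ndarray  # H x W x 2
    stains: StainMatrix

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.float64)
        if c.ndim != 3 or c.shape[2] != 2:
            raise DegenerateStainError(
                f"concentration map must be H x W x 2, got {c.shape}"
            )
        object.__setattr__(self, "c", c)


@dataclass
class NormalizationResult:
    """Normalized image plus method identifier and fit diagnostics."""

    image: np.ndarray
    method: str
    diagnostics: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Histogram matching
# ---------------------------------------------------------------------------

def _match_channel(src: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Monotone quantile mapping of one channel, ties at averaged ranks.

    Each distinct source value sits at the mid-rank quantile of its tie
    block and is sent to the first reference level whose (inclusive)
    empirical CDF reaches that quantile.  Mapping straight onto the
    reference's own levels keeps the output CDF aligned with the
    reference CDF to within half the largest tie block; interpolating
    between levels and re-rounding would instead let adjacent blocks
    collide on one level and skip its neighbor.
    """
    s_vals, s_counts = np.unique(src, return_counts=True)
    r_vals, r_counts = np.unique(ref, return_counts=True)
    s_mid = (np.cumsum(s_counts) - 0.5 * s_counts) / src.size
    r_cdf = np.cumsum(r_counts) / ref.size
    idx = np.minimum(np.searchsorted(r_cdf, s_mid, side="left"), r_vals.size - 1)
    mapped = r_vals[idx].astype(np.float64)
    return mapped[np.searchsorted(s_vals, src)]


def histogram_match(source: np.ndarray, reference: np.ndarray) -> NormalizationResult:
    """Per-channel monotone quantile mapping of source onto reference.

    The empirical CDF of each output channel agrees with the reference's
    within quantization tolerance.  A reference channel with fewer than two
    distinct values admits no meaningful mapping and is rejected.
    """
    src = np.asarray(source)
    ref = np.asarray(reference)
    out = np.empty(src.shape, dtype=np.float64)
    for ch, name in enumerate("RGB"):
        if np.unique(ref[..., ch]).size < 2:
            raise DegenerateReferenceError(
                f"reference channel {name} is constant; histogram matching "
                "is undefined"
            )
        out[..., ch] = _match_channel(
            src[..., ch].ravel(), ref[..., ch].ravel()
        ).reshape(src.shape[:2])
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return NormalizationResult(out, "histmatch", {})


# ---------------------------------------------------------------------------
# Reinhard
# ---------------------------------------------------------------------------

def reinhard(
    source: np.ndarray,
    reference: np.ndarray,
    allow_constant_channels: bool = False,
) -> NormalizationResult:
    """Moment matching in lαβ.

    Per channel: ``out = (src - mean_src) / std_src * std_ref + mean_ref``.
    Before the final clamp back to RGB the output's channel means and stds
    equal the reference's to floating-point precision; the achieved
    pre-clamp moments are recorded in the diagnostics.
    """
    lab_src = rgb_to_lab(source)
    lab_ref = rgb_to_lab(reference)
    mu_s = lab_src.mean(axis=(0, 1))
    sd_s = lab_src.std(axis=(0, 1))
    mu_r = lab_ref.mean(axis=(0, 1))
    sd_r = lab_ref.std(axis=(0, 1))
    degenerate = sd_s <= 1e-12
    if np.any(degenerate):
        if not allow_constant_channels:
            ch = "lab"[int(np.argmin(sd_s))]
            raise DegenerateSourceError(
                f"source {ch!r} channel has zero variance; pass "
                "allow_constant_channels=True to substitute std=1e-6"
            )
        sd_s = np.where(degenerate, 1e-6, sd_s)
    out_lab = (lab_src - mu_s) / sd_s * sd_r + mu_r
    diagnostics = {
        "source_mean": mu_s,
        "source_std": sd_s,
        "target_mean": mu_r,
        "target_std": sd_r,
        "pre_clamp_mean": out_lab.mean(axis=(0, 1)),
        "pre_clamp_std": out_lab.std(axis=(0, 1)),
    }
    return NormalizationResult(lab_to_rgb(out_lab), "reinhard", diagnostics)


# ---------------------------------------------------------------------------
# Macenko
# ---------------------------------------------------------------------------

def _tissue_mask(od: np.ndarray, od_threshold: float) -> np.ndarray:
    """Pixels where at least one OD channel reaches the threshold."""
    return od.max(axis=-1) >= od_threshold


def macenko_fit(
    img: np.ndarray,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    angle_percentile: float = 1.0,
    i0: float = DEFAULT_I0,
) -> StainMatrix:
    """Estimate the stain matrix by the SVD-plane extreme-angle geometry.

    Background pixels (all OD channels below ``od_threshold``) are
    discarded; the remaining OD cloud is projected onto the plane spanned
    by its top-2 right singular vectors, and the stain directions are taken
    at the ``angle_percentile``-th and ``(100 - angle_percentile)``-th
    percentiles of the projected angle distribution.
    """
    od = rgb_to_od(img, i0).reshape(-1, 3)
    tissue = od[od.max(axis=1) >= od_threshold]
    if tissue.shape[0] < MIN_TISSUE_PIXELS:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} tissue pixels above OD {od_threshold}; "
            f"need at least {MIN_TISSUE_PIXELS}"
        )
    _, s, vt = np.linalg.svd(tissue, full_matrices=False)
    if s[1] <= 1e-6 * s[0]:
        raise DegenerateStainError(
            "OD cloud is rank deficient (effectively a single stain)"
        )
    basis = vt[:2].copy()
    # Canonical signs: OD data is nonnegative, so the dominant direction can
    # be oriented into the positive octant; the second axis gets its largest
    # component made positive.  This makes the fit independent of pixel order.
    if basis[0].sum() < 0:
        basis[0] = -basis[0]
    if basis[1][np.argmax(np.abs(basis[1]))] < 0:
        basis[1] = -basis[1]
    proj = tissue @ basis.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    cols = []
    for ang in (lo, hi):
        v = np.cos(ang) * basis[0] + np.sin(ang) * basis[1]
        if v.sum() < 0:
            v = -v
        cols.append(v)
    return StainMatrix.from_columns(cols[0], cols[1])


def stain_concentrations(od: np.ndarray, stains: StainMatrix) -> ConcentrationMap:
    """Least-squares per-pixel stain amounts, negatives clamped to zero."""
    arr = np.asarray(od, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DegenerateStainError(f"OD array must be H x W x 3, got {arr.shape}")
    sv = np.linalg.svd(stains.w, compute_uv=False)
    if sv[-1] <= 1e-8 * sv[0]:
        raise DegenerateStainError("stain matrix is singular")
    pinv = np.linalg.pinv(stains.w)
    c = arr.reshape(-1, 3) @ pinv.T
    c = np.maximum(c, 0.0).reshape(arr.shape[0], arr.shape[1], 2)
    return ConcentrationMap(c, stains)


def _percentile_scales(
    conc: ConcentrationMap, od: np.ndarray, od_threshold: float, q: float
) -> np.ndarray:
    """Per-stain concentration scale at the q-th percentile over tissue pixels."""
    mask = _tissue_mask(od, od_threshold)
    pool = conc.c[mask] if mask.any() else conc.c.reshape(-1, 2)
    return np.percentile(pool, q, axis=0)


def macenko_normalize(
    source: np.ndarray,
    reference: np.ndarray,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    angle_percentile: float = 1.0,
    scale_percentile: float = 99.0,
    i0: float = DEFAULT_I0,
) -> NormalizationResult:
    """Macenko normalization: rescale stain amounts, swap in reference stains.

    Both images are fitted; source concentrations are rescaled per stain so
    their ``scale_percentile``-th percentile matches the reference's, then
    reconstructed through the reference stain matrix.  The percentile
    rescaling cancels any global concentration scale of the source.
    """
    w_src = macenko_fit(source, od_threshold, angle_percentile, i0)
    w_ref = macenko_fit(reference, od_threshold, angle_percentile, i0)
    od_src = rgb_to_od(source, i0)
    od_ref = rgb_to_od(reference, i0)
    c_src = stain_concentrations(od_src, w_src)
    c_ref = stain_concentrations(od_ref, w_ref)
    p_src = _percentile_scales(c_src, od_src, od_threshold, scale_percentile)
    p_ref = _percentile_scales(c_ref, od_ref, od_threshold, scale_percentile)
    scale = p_ref / np.maximum(p_src, 1e-12)
    od_out = (c_src.c * scale) @ w_ref.w.T
    diagnostics = {
        "source_stains": w_src,
        "reference_stains": w_ref,
        "source_percentiles": p_src,
        "reference_percentiles": p_ref,
        "scale": scale,
    }
    return NormalizationResult(od_to_rgb(od_out, i0), "macenko", diagnostics)


# ---------------------------------------------------------------------------
# Vahadane
# ---------------------------------------------------------------------------

def vahadane_fit(
    img: np.ndarray,
    sparsity: float = 0.1,
    n_iter: int = 200,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    i0: float = DEFAULT_I0,
    return_objective: bool = False,
):
    """Sparse NMF stain estimation.

    Minimizes ``||V - W H||_F^2 + sparsity * sum(H)`` over the tissue-pixel
    OD matrix ``V`` (3 x N) subject to ``H >= 0`` and ``W >= 0`` with
    unit-norm columns, by hierarchical alternating least squares started
    from the Macenko fit.  Each block update (one H row, one W column) is
    the exact minimizer of its subproblem — an L1-soft-thresholded
    projection for H, a normalized positive part for W — so the objective
    is non-increasing across iterations by construction.

    Returns ``(StainMatrix, ConcentrationMap)``, or with
    ``return_objective=True`` a third element holding the per-iteration
    objective values.
    """
    if n_iter < 1:
        raise DegenerateStainError("n_iter must be a positive integer")
    if sparsity < 0:
        raise DegenerateStainError("sparsity must be nonnegative")
    od = rgb_to_od(img, i0)
    flat = od.reshape(-1, 3)
    keep = flat.max(axis=1) >= od_threshold
    v = flat[keep].T  # 3 x N
    if v.shape[1] < MIN_TISSUE_PIXELS:
        raise InsufficientTissueError(
            f"only {v.shape[1]} tissue pixels above OD {od_threshold}; "
            f"need at least {MIN_TISSUE_PIXELS}"
        )
    w = macenko_fit(img, od_threshold, i0=i0).w.copy()
    h = np.maximum(np.linalg.pinv(w) @ v, 0.0)
    v_sq = float(np.sum(v * v))
    objective = np.empty(n_iter)
    for it in range(n_iter):
        for j in (0, 1):
            k = 1 - j
            # exact minimizer of the H-row subproblem (w_j has unit norm)
            h[j] = np.maximum(
                w[:, j] @ v - (w[:, j] @ w[:, k]) * h[k] - 0.5 * sparsity, 0.0
            )
            # exact minimizer of the W-column subproblem on the nonneg sphere
            g = v @ h[j] - w[:, k] * (h[k] @ h[j])
            g = np.maximum(g, 0.0)
            norm = np.linalg.norm(g)
            if norm > 1e-12:
                w[:, j] = g / norm
        gram = v @ h.T  # 3 x 2
        cross = h @ h.T  # 2 x 2
        objective[it] = float(
            v_sq - 2.0 * np.sum(w * gram) + np.sum((w.T @ w) * cross)
            + sparsity * h.sum()
        )
    stains = StainMatrix(_order_he(np.maximum(w, 0.0) / np.linalg.norm(w, axis=0)))
    conc = stain_concentrations(od, stains)
    if return_objective:
        return stains, conc, objective
    return stains, conc


def vahadane_normalize(
    source: np.ndarray,
    reference: np.ndarray,
    sparsity: float = 0.1,
    n_iter: int = 200,
    scale_percentile: float = 99.0,
    od_threshold: float = DEFAULT_OD_THRESHOLD,
    i0: float = DEFAULT_I0,
) -> NormalizationResult:
    """Vahadane normalization.

    Source stain density is percentile-rescaled to the reference's and
    recombined with the reference color appearance (its fitted stain
    matrix).  Background pixels carry near-zero concentrations and so
    reconstruct to white.
    """
    w_src, c_src = vahadane_fit(source, sparsity, n_iter, od_threshold, i0)
    w_ref, c_ref = vahadane_fit(reference, sparsity, n_iter, od_threshold, i0)
    od_src = rgb_to_od(source, i0)
    od_ref = rgb_to_od(reference, i0)
    p_src = _percentile_scales(c_src, od_src, od_threshold, scale_percentile)
    p_ref = _percentile_scales(c_ref, od_ref, od_threshold, scale_percentile)
    scale = p_ref / np.maximum(p_src, 1e-12)
    od_out = (c_src.c * scale) @ w_ref.w.T
    diagnostics = {
        "source_stains": w_src,
        "reference_stains": w_ref,
        "source_percentiles": p_src,
        "reference_percentiles": p_ref,
        "scale": scale,
    }
    return NormalizationResult(od_to_rgb(od_out, i0), "vahadane", diagnostics)
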