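"""Synthetic multi-laboratory H&E slide generator.

Emulates the study design in which sections of one tissue block are
stained by many laboratories: a single :class:`TissueField` (per-pixel
hematoxylin-binding and eosin-binding material) is rendered under per-lab
staining conditions — a jittered stain matrix, over-/under-staining scale
factors, a smooth multiplicative unevenness field, and a small background
tint — through the Beer-Lambert optical-density model.  Ground truth (the
stain matrix and scales of every virtual lab) is retained so that stain
estimation and normalization can be validated end to end.

Morphology is deliberately schematic (elliptical nuclei on textured
cytoplasm with lumen holes and a white margin): the generator reproduces
the *color* statistics that drive stain normalization, not organ-specific
histology.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy.ndimage import gaussian_filter, label

from .color import DEFAULT_I0, od_to_rgb
from .exceptions import InvalidImageError
from .normalize import StainMatrix

__all__ = [
    "CANONICAL_HE",
    "TissueField",
    "LabStainProfile",
    "PanelVariation",
    "SyntheticPanel",
    "make_tissue",
    "make_lab_profile",
    "render_slide",
    "make_panel",
    "count_nuclei",
]

#: Canonical H&E OD directions (unit-normalized), from a widely used
#: real-slide calibration: hematoxylin absorbs red/green more than blue
#: (nuclei transmit blue-purple), eosin absorbs green and blue (tissue
#: transmits pink-red).  Real eosin carries appreciable red and blue
#: absorption, which is what gives H&E its broad intensity range.
CANONICAL_HE = StainMatrix.from_columns(
    np.array([0.5626, 0.7201, 0.4062]), np.array([0.2159, 0.8012, 0.5581])
)

#: Minimum hematoxylin density inside nuclei.
NUCLEUS_FLOOR = 0.8


@dataclass
class TissueField:
    """Shared morphology: per-pixel stain-binding densities and nucleus mask."""

    h_density: np.ndarray
    e_density: np.ndarray
    nucleus_mask: np.ndarray
    seed: int


@dataclass
class LabStainProfile:
    """One virtual laboratory's staining conditions, with ground truth."""

    stains: StainMatrix
    h_scale: float = 1.0
    e_scale: float = 1.0
    unevenness: np.ndarray | None = None  # multiplicative field, or None
    background_tint: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed: int = 0


@dataclass
class PanelVariation:
    """Breadth of inter-laboratory variation.

    ``spread`` is the angular standard deviation (radians) of the stain
    vector jitter; ``scale_sigma`` the log-normal sigma of the over-/
    under-staining factors; ``unevenness`` the amplitude u of the smooth
    multiplicative field in [1-u, 1+u]; ``tint`` the maximum per-channel
    background OD offset.
    """

    spread: float = 0.2
    scale_sigma: float = 0.25
    unevenness: float = 0.15
    tint: float = 0.02


@dataclass
class SyntheticPanel:
    """One tissue rendered by every virtual lab, with ground truth kept."""

    tissue: TissueField
    labs: list[LabStainProfile]
    images: list[np.ndarray]
    ids: list[str]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float):
    """Zero-mean smooth noise scaled to peak magnitude 1."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def make_tissue(
    height: int = 512,
    width: int = 512,
    nucleus_count: int = 400,
    seed: int = 0,
    nucleus_floor: float = NUCLEUS_FLOOR,
) -> TissueField:
    """Generate a seeded tissue morphology.

    A wobbly elliptical tissue region (leaving a white margin) carries a
    textured eosin-binding cytoplasm with lumen holes and a faint
    hematoxylin background; ``nucleus_count`` elliptical nuclei with high
    hematoxylin density and strongly suppressed eosin are placed with a
    minimum center spacing so they stay individually resolvable.
    """
    if height < 64 or width < 64:
        raise InvalidImageError("tissue dimensions must be at least 64 x 64")
    if nucleus_count < 0:
        raise InvalidImageError("nucleus_count must be nonnegative")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    r = np.sqrt(((yy - cy) / (0.62 * height)) ** 2 + ((xx - cx) / (0.62 * width)) ** 2)
    wobble = _smooth_field(rng, (height, width), sigma=min(height, width) / 8)
    tissue = r + 0.12 * wobble <= 1.0

    lum_field = gaussian_filter(
        rng.standard_normal((height, width)), sigma=min(height, width) / 24
    )
    if tissue.any():
        lumen = tissue & (lum_field > np.quantile(lum_field[tissue], 0.90))
    else:
        lumen = np.zeros_like(tissue)
    solid = tissue & ~lumen

    # Texture at several scales — coarse staining bands, mid-scale structure,
    # fine granularity, and per-pixel grain emulating sub-resolution chromatin
    # and eosinophilia variation — so rendered intensities span the
    # quasi-continuous range real tissue shows instead of collapsing onto a
    # few gray levels.  Cytoplasm carries faint basophilia (hematoxylin
    # uptake), as connective tissue and smooth muscle do.
    fine = 0.5 * (1.0 + _smooth_field(rng, (height, width), sigma=1.2))
    tex = 0.5 * (1.0 + _smooth_field(rng, (height, width), sigma=4))
    bands = 0.5 * (1.0 + _smooth_field(rng, (height, width), sigma=16))
    grain_e = rng.uniform(0.6, 1.4, (height, width))
    grain_h = rng.uniform(0.5, 1.5, (height, width))
    grain_n = rng.uniform(0.0, 1.0, (height, width))
    e_density = (0.15 + 0.9 * (0.4 * fine + 0.3 * tex + 0.3 * bands)) * solid
    fine_h = 0.5 * (1.0 + _smooth_field(rng, (height, width), sigma=1.2))
    h_density = (0.02 + 0.05 * (0.4 * fine_h + 0.3 * tex + 0.3 * bands)) * solid

    nucleus_mask = np.zeros((height, width), dtype=bool)
    if nucleus_count > 0 and solid.any():
        max_radius = 7.5
        min_spacing = 2.0 * max_radius + 2.0  # no two ellipses can touch
        margin = int(max_radius) + 2
        interior = solid[margin : height - margin, margin : width - margin]
        cand_y, cand_x = np.nonzero(interior)
        cand_y, cand_x = cand_y + margin, cand_x + margin
        order = rng.permutation(cand_y.size)
        acc_y = np.empty(nucleus_count)
        acc_x = np.empty(nucleus_count)
        n_acc = 0
        spacing_sq = min_spacing**2
        for idx in order:
            if n_acc >= nucleus_count:
                break
            py, px = float(cand_y[idx]), float(cand_x[idx])
            if n_acc and np.min(
                (acc_y[:n_acc] - py) ** 2 + (acc_x[:n_acc] - px) ** 2
            ) < spacing_sq:
                continue
            acc_y[n_acc], acc_x[n_acc] = py, px
            n_acc += 1
            a = rng.uniform(3.5, max_radius)
            b = rng.uniform(2.5, a)
            theta = rng.uniform(0, np.pi)
            purity = rng.uniform(0.0, 0.15)  # residual eosin inside the nucleus
            y0, y1 = int(py - max_radius) - 1, int(py + max_radius) + 2
            x0, x1 = int(px - max_radius) - 1, int(px + max_radius) + 2
            ly, lx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
            dy, dx = ly - py, lx - px
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            patch = np.s_[y0:y1, x0:x1]
            nucleus_mask[patch] |= inside
            h_density[patch] = np.where(
                inside, nucleus_floor + 0.28, h_density[patch]
            )
            e_density[patch] = np.where(
                inside, e_density[patch] * purity, e_density[patch]
            )
    # Scanner point-spread blur of the base structure: fills the intensity
    # gap between the nuclear and cytoplasmic bands with edge-ramp values,
    # as real optics do.  Applied before the grain so sub-resolution
    # granularity survives at full amplitude.
    h_density = gaussian_filter(h_density, sigma=0.7)
    e_density = gaussian_filter(e_density, sigma=0.7)
    e_density *= grain_e
    h_density *= grain_h
    if nucleus_mask.any():
        h_density[nucleus_mask] = (
            nucleus_floor + 0.08 + 0.45 * grain_n[nucleus_mask]
        )
    # Faint stain-residue film over the slide: real backgrounds are never a
    # single gray level.  A clean 3-pixel frame is kept at exactly zero
    # density (the white margin outside the coverslipped area).
    interior_frame = np.zeros((height, width), dtype=bool)
    interior_frame[3:-3, 3:-3] = True
    h_density += 0.05 * rng.uniform(0.0, 1.0, (height, width))
    e_density += 0.05 * rng.uniform(0.0, 1.0, (height, width))
    h_density *= interior_frame
    e_density *= interior_frame
    nucleus_mask &= interior_frame
    return TissueField(h_density, e_density, nucleus_mask, seed)


def _jitter_direction(
    rng: np.random.Generator, v: np.ndarray, spread: float
) -> np.ndarray:
    """Rotate a unit OD direction by a random angle ~ N(0, spread) radians."""
    if spread == 0.0:
        return v.copy()
    # random tangent direction
    t = rng.standard_normal(3)
    t -= (t @ v) * v
    norm = np.linalg.norm(t)
    if norm < 1e-12:
        return v.copy()
    t /= norm
    angle = rng.normal(0.0, spread)
    out = np.cos(angle) * v + np.sin(angle) * t
    out = np.maximum(out, 0.0)
    n = np.linalg.norm(out)
    return out / n if n > 1e-12 else v.copy()


def make_lab_profile(
    shape: tuple[int, int],
    seed: int,
    variation: PanelVariation | None = None,
    base: StainMatrix = CANONICAL_HE,
) -> LabStainProfile:
    """Draw one laboratory's staining conditions.

    Stain vectors are jittered around the canonical H&E directions
    (re-drawn if the jitter would swap the hematoxylin/eosin identities,
    since real labs vary their stains but do not exchange them), scales are
    log-normal so extreme over-/under-staining occurs but is rare, and the
    unevenness field is smooth at roughly a quarter of the slide scale.
    """
    if variation is None:
        variation = PanelVariation()
    rng = np.random.default_rng(seed)
    for _ in range(100):
        h = _jitter_direction(rng, base.hematoxylin, variation.spread)
        e = _jitter_direction(rng, base.eosin, variation.spread)
        # keep the H/E identity: hematoxylin stays the red-dominant-OD column
        if (h[0] - h[2]) > (e[0] - e[2]):
            break
    stains = StainMatrix(np.stack([h, e], axis=1))
    h_scale = float(rng.lognormal(0.0, variation.scale_sigma))
    e_scale = float(rng.lognormal(0.0, variation.scale_sigma))
    unevenness = None
    if variation.unevenness > 0.0:
        u = _smooth_field(rng, shape, sigma=min(shape) / 4)
        unevenness = 1.0 + variation.unevenness * u
    tint = rng.uniform(0.0, variation.tint, size=3) if variation.tint > 0 else np.zeros(3)
    return LabStainProfile(stains, h_scale, e_scale, unevenness, tint, seed)


def render_slide(
    tissue: TissueField, lab: LabStainProfile, i0: float = DEFAULT_I0
) -> np.ndarray:
    """Render a tissue field under one lab's staining via Beer-Lambert.

    ``od = stains @ (h_scale * h, e_scale * e)`` per pixel, modulated by
    the unevenness field and offset by the background tint, then converted
    back to RGB.  Zero-density pixels with zero tint render as white.
    """
    conc = np.stack(
        [lab.h_scale * tissue.h_density, lab.e_scale * tissue.e_density], axis=-1
    )
    od = conc @ lab.stains.w.T
    if lab.unevenness is not None:
        od = od * lab.unevenness[..., None]
    od = od + lab.background_tint
    return od_to_rgb(np.maximum(od, 0.0), i0)


def make_panel(
    n_labs: int = 20,
    height: int = 512,
    width: int = 512,
    nucleus_count: int = 400,
    variation: PanelVariation | None = None,
    seed: int = 17,
    i0: float = DEFAULT_I0,
) -> SyntheticPanel:
    """Generate a full multi-laboratory panel with ground truth.

    One tissue field is rendered by ``n_labs`` virtual laboratories.  Lab 0
    always uses the canonical, balanced profile (no jitter, unit scales,
    even staining, no tint) so the panel contains a meaningful reference
    candidate; the rest are drawn from the variation distributions.
    """
    if n_labs < 2:
        raise InvalidImageError("a panel needs at least 2 labs")
    if variation is None:
        variation = PanelVariation()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_labs + 1)
    tissue = make_tissue(height, width, nucleus_count, seed=int(child_seeds[0]))
    labs = [LabStainProfile(CANONICAL_HE, seed=int(child_seeds[1]))]
    labs += [
        make_lab_profile((height, width), int(child_seeds[i + 1]), variation)
        for i in range(1, n_labs)
    ]
    images = [render_slide(tissue, lab, i0) for lab in labs]
    ids = [f"lab{i:02d}" for i in range(n_labs)]
    return SyntheticPanel(tissue, labs, images, ids)


def count_nuclei(mask: np.ndarray) -> int:
    """Connected components (8-connectivity) of a nucleus mask."""
    _, n = label(mask, structure=np.ones((3, 3), dtype=int))
    return int(n)
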