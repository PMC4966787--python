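"""Synthetic Feulgen-stained slide generator.

Renders transmitted-light images of spread (monolayer) preparations in
which every nucleus deposits a known total absorbance proportional to its
DNA mass — the Feulgen premise that bound stain tracks DNA 1:1. Each
rendered nucleus is returned with a ground-truth record, so the whole
measurement pipeline (OD transform, segmentation, densitometry,
calibration) can be validated against known per-nucleus DNA content
without any acquired image data.

The generator emulates:

* a diploid human population at 2C = 6 pg with biological spread,
* chicken red-blood-cell (cRBC) calibration standards at 2C = 2.5 pg,
* sub-diploid populations (1–3 pg) as found in osteoclasts and syncytia,
* nuclear area roughly proportional to DNA content,
* center-weighted chromatin texture (so the densitometric SD is nonzero),
* additive detector noise and an optional low-order illumination field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .optics import DEFAULT_SCALE, TransmittedLightImage

logger = logging.getLogger(__name__)

SHAPE_CLASSES = ("ellipse", "cigar", "bell", "syncytium", "multinucleated")

CRBC_2C_PG = 2.5
"""DNA mass of a chicken erythrocyte nucleus (2C), in pg."""

CRBC_MEAN_AREA_UM2 = 25.9
"""Typical cRBC nuclear area in a spread smear, in square micrometres."""

DEFAULT_AREA_PER_PG = CRBC_MEAN_AREA_UM2 / CRBC_2C_PG  # 10.36 um^2 per pg


@dataclass
class Population:
    """One nucleus population on a slide.

    ``mean_pg``/``sd_pg`` give the DNA-content distribution (normal,
    truncated at a small positive floor); ``count`` nuclei are rendered
    with the given morphology class.
    """

    mean_pg: float
    sd_pg: float
    count: int
    shape_class: str = "ellipse"
    stain_cv: float = 0.0
    """CV of per-nucleus multiplicative staining variability: the deposited
    absorbance is ``stain_factor × pg × lognormal(1, stain_cv)`` while the
    recorded true DNA stays ``pg`` (used for constant-DNA standards whose
    measured IOD still spreads)."""

    def __post_init__(self) -> None:
        if self.mean_pg <= 0:
            raise ValueError("mean_pg must be positive")
        if self.sd_pg < 0 or self.stain_cv < 0:
            raise ValueError("sd_pg and stain_cv must be non-negative")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape_class {self.shape_class!r}")


@dataclass
class SlideSpec:
    """Recipe for a synthetic slide.

    Parameters
    ----------
    image_shape
        (rows, cols) in pixels, or None to auto-size the canvas so the
        requested nuclei occupy roughly 12% of it.
    scale
        Pixels per square micrometre.
    i0
        White-reference intensity in detector units (must fit the bit depth).
    stain_factor
        Absorbance (OD·pixel) deposited per pg of DNA. With the defaults a
        diploid nucleus has a mean intra-nuclear OD near 0.3.
    populations
        Nucleus populations to render.
    area_per_pg
        Nuclear area per pg of DNA (um^2/pg); areas get multiplicative
        lognormal noise of CV ``area_noise_cv``.
    noise_sd
        Additive Gaussian intensity noise SD, clipped to [0, i0].
    illumination_gradient
        Optional (row_slope, col_slope) of a linear relative illumination
        field centred at 1.0 in the image centre, or None for flat light.
    texture_strength
        Amplitude of the center-weighted radial chromatin profile.
    texture_noise_cv
        CV of multiplicative per-pixel texture noise inside nuclei.
    bit_depth
        8 or 16; output images are unsigned integers of this depth.
    seed
        RNG seed; fixed seed gives a bit-identical render.
    """

    image_shape: tuple[int, int] | None = None
    scale: float = DEFAULT_SCALE
    i0: float = 30000.0
    stain_factor: float = 300.0
    populations: list[Population] = field(
        default_factory=lambda: [Population(6.0, 0.6, 60, "ellipse")]
    )
    area_per_pg: float = DEFAULT_AREA_PER_PG
    area_noise_cv: float = 0.10
    noise_sd: float = 50.0
    illumination_gradient: tuple[float, float] | None = None
    texture_strength: float = 0.5
    texture_noise_cv: float = 0.10
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stain_factor <= 0:
            raise ValueError("stain_factor must be positive")
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.i0 > 2**self.bit_depth - 1:
            raise ValueError("i0 exceeds the dynamic range of bit_depth")
        if self.noise_sd < 0 or self.area_noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.area_per_pg <= 0 or self.scale <= 0:
            raise ValueError("area_per_pg and scale must be positive")


@dataclass
class GroundTruthRecord:
    """Truth for one rendered nucleus."""

    nucleus_id: int
    true_pg: float
    shape_class: str
    centroid_row: float
    centroid_col: float
    true_area_um2: float
    group_id: int | None = None  # syncytium chain / multinucleated cluster


# ---------------------------------------------------------------------------
# footprint builders — each returns a boolean mask on a local grid


def _ellipse_mask(area_px: float, axis_ratio: float, theta: float) -> np.ndarray:
    a = math.sqrt(area_px / (math.pi * axis_ratio))
    b = axis_ratio * a
    half = int(math.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _bell_mask(area_px: float, theta: float) -> np.ndarray:
    # annulus (cup seen in projection): outer R, inner 0.55 R
    inner_frac = 0.55
    r_out = math.sqrt(area_px / (math.pi * (1 - inner_frac**2)))
    r_in = inner_frac * r_out
    half = int(math.ceil(r_out)) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    rr = np.hypot(xx, yy)
    mask = (rr <= r_out) & (rr >= r_in)
    # open the cup on one side so it is a bell, not a closed ring
    ct, st = math.cos(theta), math.sin(theta)
    mask &= (xx * ct + yy * st) < 0.6 * r_out
    return mask


def _radial_profile(mask: np.ndarray, strength: float) -> np.ndarray:
    """Center-weighted chromatin weighting on a footprint.

    Uses the Euclidean distance to the footprint edge so it adapts to any
    shape; weight is 1 at the rim and 1 + strength at the deepest point.
    """
    from scipy import ndimage as ndi

    dist = ndi.distance_transform_edt(mask)
    dmax = dist.max()
    if dmax == 0:
        return mask.astype(float)
    return np.where(mask, 1.0 + strength * dist / dmax, 0.0)


class _Placer:
    """Non-overlapping random placement with a retry budget."""

    def __init__(self, shape: tuple[int, int], rng: np.random.Generator,
                 margin: int = 2, retries: int = 200) -> None:
        self.occ = np.zeros(shape, dtype=bool)
        self.rng = rng
        self.margin = margin
        self.retries = retries

    def place(self, mask: np.ndarray) -> tuple[int, int] | None:
        from scipy import ndimage as ndi

        grown = ndi.binary_dilation(mask, iterations=self.margin)
        h, w = mask.shape
        H, W = self.occ.shape
        if h + 2 > H or w + 2 > W:
            raise ValueError("nucleus larger than image")
        for _ in range(self.retries):
            r = int(self.rng.integers(1, H - h - 1))
            c = int(self.rng.integers(1, W - w - 1))
            region = self.occ[r : r + h, c : c + w]
            if not np.any(region & grown):
                region |= grown
                return r, c
        return None


def _auto_shape(spec: SlideSpec, packing: float = 0.12) -> tuple[int, int]:
    total_px = 0.0
    for pop in spec.populations:
        total_px += pop.count * pop.mean_pg * spec.area_per_pg * spec.scale
    side = int(math.sqrt(max(total_px, 1.0) / packing)) + 64
    side = max(side, 256)
    return (side, side)


def _draw_pg(rng: np.random.Generator, pop: Population) -> float:
    pg = rng.normal(pop.mean_pg, pop.sd_pg)
    return max(pg, 0.05)


def _stain_multiplier(rng: np.random.Generator, pop: Population) -> float:
    if pop.stain_cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1 + pop.stain_cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma)


def _draw_footprint(rng, spec: SlideSpec, pop: Population, pg: float) -> np.ndarray:
    area_um2 = pg * spec.area_per_pg
    if spec.area_noise_cv > 0:
        sigma = math.sqrt(math.log(1 + spec.area_noise_cv**2))
        area_um2 *= rng.lognormal(-0.5 * sigma**2, sigma)
    area_px = max(area_um2 * spec.scale, 4.0)
    theta = rng.uniform(0, math.pi)
    if pop.shape_class == "cigar":
        ratio = rng.uniform(0.25, 0.40)  # eccentricity >= 0.9
        return _ellipse_mask(area_px, ratio, theta)
    if pop.shape_class == "bell":
        return _bell_mask(area_px, theta)
    ratio = rng.uniform(0.80, 1.0)  # eccentricity <= 0.6
    return _ellipse_mask(area_px, ratio, theta)


def _deposit(
    absorbance: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int],
    total_od: float,
    spec: SlideSpec,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Paint ``total_od`` absorbance over the footprint; return centroid+area."""
    weights = _radial_profile(mask, spec.texture_strength)
    if spec.texture_noise_cv > 0:
        sigma = math.sqrt(math.log(1 + spec.texture_noise_cv**2))
        weights = weights * rng.lognormal(0.0, sigma, size=weights.shape)
        weights[~mask] = 0.0
    weights *= total_od / weights.sum()
    r, c = offset
    h, w = mask.shape
    absorbance[r : r + h, c : c + w] += weights
    rows, cols = np.nonzero(mask)
    return (r + rows.mean(), c + cols.mean(), int(mask.sum()))


def render_slide(
    spec: SlideSpec,
) -> tuple[TransmittedLightImage, list[GroundTruthRecord]]:
    """Render a slide and its per-nucleus ground truth.

    The rendered intensity is ``I = i0 · L(x, y) · 10^(−A) + noise`` with
    ``A`` the summed absorbance field; before noise and quantisation the
    absorbance integrated over each nucleus equals ``stain_factor ×
    true_pg`` exactly. Nuclei that cannot be placed without overlap within
    the retry budget are skipped with a warning and excluded from truth.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape or _auto_shape(spec)
    absorbance = np.zeros(shape, dtype=float)
    placer = _Placer(shape, rng)
    records: list[GroundTruthRecord] = []
    nucleus_id = 0
    group_id = 0

    for pop in spec.populations:
        if pop.shape_class in ("syncytium", "multinucleated"):
            remaining = pop.count
            while remaining > 0:
                if pop.shape_class == "syncytium":
                    k = int(rng.integers(4, 11))
                else:
                    k = int(rng.integers(2, 21))
                k = min(k, remaining)
                placed = _render_group(
                    absorbance, placer, rng, spec, pop, k, nucleus_id, group_id
                )
                records.extend(placed)
                nucleus_id += len(placed)
                group_id += 1
                remaining -= k
        else:
            for _ in range(pop.count):
                pg = _draw_pg(rng, pop)
                mask = _draw_footprint(rng, spec, pop, pg)
                pos = placer.place(mask)
                if pos is None:
                    logger.warning(
                        "could not place a %s nucleus (%.2f pg); skipped",
                        pop.shape_class, pg,
                    )
                    continue
                total_od = spec.stain_factor * pg * _stain_multiplier(rng, pop)
                crow, ccol, npx = _deposit(
                    absorbance, mask, pos, total_od, spec, rng
                )
                records.append(GroundTruthRecord(
                    nucleus_id, pg, pop.shape_class, crow, ccol,
                    npx / spec.scale,
                ))
                nucleus_id += 1

    image = _expose(absorbance, spec, rng)
    return image, records


def _render_group(
    absorbance, placer, rng, spec: SlideSpec, pop: Population,
    k: int, first_id: int, group_id: int,
) -> list[GroundTruthRecord]:
    """Render a chain (syncytium) or cluster (multinucleated) of k nuclei.

    The member footprints are assembled on one local canvas with >=2 px
    gaps so they stay individually segmentable, then placed as a unit.
    """
    pgs = [_draw_pg(rng, pop) for _ in range(k)]
    masks = [_draw_footprint(rng, spec, Population(
        pop.mean_pg, pop.sd_pg, 1, "ellipse"), pg) for pg in pgs]
    gap = 3
    if pop.shape_class == "syncytium":
        # linear chain with a slowly wandering direction
        heading = rng.uniform(0, 2 * math.pi)
        positions = [(0.0, 0.0)]
        for i in range(1, k):
            heading += rng.normal(0, 0.35)
            step = (masks[i - 1].shape[0] + masks[i].shape[0]) / 2 + gap
            pr, pc = positions[-1]
            positions.append((pr + step * math.sin(heading),
                              pc + step * math.cos(heading)))
    else:
        # cluster inside a disc
        disc_r = gap + math.sqrt(sum(m.sum() for m in masks)) * 1.3
        positions = [(0.0, 0.0)]
        for i in range(1, k):
            for _ in range(100):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0, disc_r)
                cand = (rad * math.sin(ang), rad * math.cos(ang))
                if all(math.hypot(cand[0] - p[0], cand[1] - p[1])
                       > (masks[i].shape[0] + masks[j].shape[0]) / 2 + gap
                       for j, p in enumerate(positions)):
                    break
            positions.append(cand)

    # assemble on a local canvas
    offs = []
    min_r = min(p[0] - m.shape[0] / 2 for p, m in zip(positions, masks))
    min_c = min(p[1] - m.shape[1] / 2 for p, m in zip(positions, masks))
    max_r = max(p[0] + m.shape[0] / 2 for p, m in zip(positions, masks))
    max_c = max(p[1] + m.shape[1] / 2 for p, m in zip(positions, masks))
    H = int(max_r - min_r) + 4
    W = int(max_c - min_c) + 4
    canvas = np.zeros((H, W), dtype=bool)
    for (pr, pc), m in zip(positions, masks):
        r0 = int(pr - min_r - m.shape[0] / 2) + 2
        c0 = int(pc - min_c - m.shape[1] / 2) + 2
        r0 = max(0, min(r0, H - m.shape[0]))
        c0 = max(0, min(c0, W - m.shape[1]))
        canvas[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]] |= m
        offs.append((r0, c0))

    pos = placer.place(canvas)
    if pos is None:
        logger.warning("could not place a %s group of %d nuclei; skipped",
                       pop.shape_class, k)
        return []
    out = []
    for i, (m, pg) in enumerate(zip(masks, pgs)):
        off = (pos[0] + offs[i][0], pos[1] + offs[i][1])
        total_od = spec.stain_factor * pg * _stain_multiplier(rng, pop)
        crow, ccol, npx = _deposit(
            absorbance, m, off, total_od, spec, rng)
        out.append(GroundTruthRecord(
            first_id + i, pg, pop.shape_class, crow, ccol,
            npx / spec.scale, group_id=group_id,
        ))
    return out


def _expose(absorbance: np.ndarray, spec: SlideSpec,
            rng: np.random.Generator) -> TransmittedLightImage:
    shape = absorbance.shape
    if spec.illumination_gradient is not None:
        gr, gc = spec.illumination_gradient
        rows = (np.arange(shape[0]) - shape[0] / 2)[:, None] / shape[0]
        cols = (np.arange(shape[1]) - shape[1] / 2)[None, :] / shape[1]
        light = 1.0 + gr * rows + gc * cols
        light = np.clip(light, 0.0, None)
    else:
        light = 1.0
    intensity = spec.i0 * light * 10.0 ** (-absorbance)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0, spec.noise_sd, size=shape)
    intensity = np.clip(intensity, 0.0, spec.i0)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    pixels = np.rint(intensity).astype(dtype)
    return TransmittedLightImage(pixels=pixels, scale=spec.scale, i0=spec.i0)


def standard_smear_spec(
    count: int,
    seed: int = 0,
    *,
    mean_area_um2: float = CRBC_MEAN_AREA_UM2,
    iod_cv: float = 0.23,
    **overrides,
) -> SlideSpec:
    """SlideSpec for a cRBC calibration smear.

    All nuclei carry exactly 2C = 2.5 pg of DNA (``true_pg`` is constant);
    the per-nucleus integrated-absorbance spread (default CV 23%) models
    staining variability around that constant value. ``mean_area_um2``
    (default 25.9) sets the typical cRBC nuclear footprint.
    """
    if count < 1:
        raise ValueError("standard smear must contain at least one nucleus")
    spec = SlideSpec(
        populations=[
            Population(CRBC_2C_PG, 0.0, count, "ellipse", stain_cv=iod_cv)
        ],
        area_per_pg=mean_area_um2 / CRBC_2C_PG,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def render_standard_smear(
    count: int, seed: int = 0, **overrides
) -> tuple[TransmittedLightImage, list[GroundTruthRecord]]:
    """Render a cRBC standard smear; see :func:`standard_smear_spec`."""
    return render_slide(standard_smear_spec(count, seed, **overrides))
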