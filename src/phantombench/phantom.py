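"""Synthetic anthropomorphic slice generation.

Produces ensembles of 8-bit grayscale coronal breast-phantom slices with a
known per-pixel tissue layout (background, fat, glandular, skin, ligament),
one of four BI-RADS-style density classes (fatty, scattered, heterogeneous,
dense) at a configurable prevalence, and prescribed per-tissue intensity
laws: affine-scaled Beta distributions, textured by Gaussian smoothing and
restored to the exact marginal by rank matching.

The layout is procedural: a perturbed-superellipse breast outline, a thin
skin band at the periphery, a Cooper-ligament network obtained by
skeletonizing the Voronoi tessellation of Poisson-sampled interior seeds,
and glandular tissue allocated to tessellation cells until the class target
glandular fraction is met.  Heterogeneous layouts additionally receive
spiculated ("burst"-like) glandular components.
"""

from __future__ import annotations

import dataclasses
import functools
import math
import os
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import beta as beta_dist
from skimage.morphology import skeletonize

# Tissue label coding shared with the segmentation module.
BACKGROUND, FAT, GLANDULAR, SKIN, LIGAMENT = 0, 1, 2, 3, 4
TISSUE_NAMES = {FAT: "fat", GLANDULAR: "glandular", SKIN: "skin", LIGAMENT: "ligament"}

CLASSES = ("fatty", "scattered", "heterogeneous", "dense")

#: Glandular-fraction bands per class, left-closed: fraction g = G/(G+F).
DEFAULT_CLASS_BANDS = {
    "fatty": (0.0, 0.20),
    "scattered": (0.20, 0.40),
    "heterogeneous": (0.40, 0.65),
    "dense": (0.65, 1.0),
}

#: Per-class glandular-fraction targets (band midpoints, dense kept moderate).
DEFAULT_CLASS_TARGETS = {
    "fatty": 0.10,
    "scattered": 0.30,
    "heterogeneous": 0.52,
    "dense": 0.75,
}


@dataclasses.dataclass(frozen=True)
class TissueLaw:
    """Affine-scaled Beta intensity law: b + a * X with X ~ Beta(alpha, beta)."""

    scale: float
    offset: float
    alpha: float
    beta: float

    @property
    def support(self) -> tuple[float, float]:
        return (self.offset, self.offset + self.scale)

    def ppf(self, q: np.ndarray) -> np.ndarray:
        return self.offset + self.scale * beta_dist.ppf(q, self.alpha, self.beta)

    def rvs(self, size, rng: np.random.Generator) -> np.ndarray:
        return self.offset + self.scale * rng.beta(self.alpha, self.beta, size=size)


@dataclasses.dataclass(frozen=True)
class IntensityModel:
    """Per-tissue intensity laws plus the texture-smoothing parameter.

    Defaults are the challenge prescription: fat ~ 60 X + 52 with
    X ~ Beta(2, 4); glandular ~ 96 X + 128, Beta(4, 2); skin ~ 16 X + 228,
    Beta(3, 3); ligament ~ 16 X + 232, Beta(3, 3); Gaussian sigma = 0.8 px.
    """

    fat: TissueLaw = TissueLaw(60, 52, 2, 4)
    glandular: TissueLaw = TissueLaw(96, 128, 4, 2)
    skin: TissueLaw = TissueLaw(16, 228, 3, 3)
    ligament: TissueLaw = TissueLaw(16, 232, 3, 3)
    sigma: float = 0.8
    bit_depth: int = 8

    def law(self, label: int) -> TissueLaw:
        return {FAT: self.fat, GLANDULAR: self.glandular,
                SKIN: self.skin, LIGAMENT: self.ligament}[label]

    def __post_init__(self) -> None:
        hi = 2 ** self.bit_depth - 1
        for lbl in (FAT, GLANDULAR, SKIN, LIGAMENT):
            lo, up = self.law(lbl).support
            if lo < 0 or up > hi:
                raise ValueError(
                    f"{TISSUE_NAMES[lbl]} law support [{lo}, {up}] exceeds "
                    f"[0, {hi}]"
                )


@dataclasses.dataclass
class GeneratorConfig:
    """Ensemble-generation configuration.

    ``prevalence`` is the fatty:scattered:heterogeneous:dense mix (normalized
    internally); ``ligament_seed_density`` is the expected number of Voronoi
    seeds per interior pixel and controls ligament-network fineness.
    """

    image_size: int = 512
    n_images: int = 100
    prevalence: tuple[float, float, float, float] = (1, 4, 4, 1)
    class_targets: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_TARGETS))
    class_bands: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_BANDS))
    ligament_seed_density: float = 7e-4
    fraction_tol: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        p = np.asarray(self.prevalence, dtype=float)
        if p.min() < 0 or p.sum() <= 0:
            raise ValueError("prevalence must be non-negative with positive sum")
        self.prevalence = tuple(p / p.sum())


@dataclasses.dataclass
class TissueLayout:
    """Per-pixel tissue label map plus class metadata (generation ground truth)."""

    label_map: np.ndarray  # (H, W) uint8 with labels 0..4
    breast_class: str
    glandular_fraction: float

    def tissue_mask(self, label: int) -> np.ndarray:
        return self.label_map == label


def class_allocation(n: int, prevalence: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``n`` images to the four classes.

    Ties in the remainders are broken in class order
    (fatty, scattered, heterogeneous, dense).
    """
    p = np.asarray(prevalence, dtype=float)
    p = p / p.sum()
    raw = n * p
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    # stable sort => earlier class wins remainder ties
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return counts.tolist()


def _breast_outline(size: int, rng: np.random.Generator) -> np.ndarray:
    """Filled, star-convex, egg-like breast mask centered in the frame."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = size / 2.0, size / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # superellipse semi-axes and exponent, mildly randomized
    a = size * rng.uniform(0.33, 0.40)  # horizontal
    b = size * rng.uniform(0.37, 0.44)  # vertical
    n = rng.uniform(2.0, 3.0)
    ct, st = np.cos(theta), np.sin(theta)
    base = (np.abs(ct / a) ** n + np.abs(st / b) ** n) ** (-1.0 / n)

    # low-order radial perturbation plus a slight egg taper
    pert = np.ones_like(theta)
    for k in (2, 3, 4, 5):
        amp = rng.uniform(0, 0.035) / k * 2
        pert += amp * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
    pert += 0.05 * rng.uniform(0.5, 1.5) * np.sin(theta)  # vertical asymmetry
    radius = base * pert
    return r <= radius


def sample_layout(breast_class: str, config: GeneratorConfig,
                  rng: np.random.Generator, max_retries: int = 8) -> TissueLayout:
    """Draw one tissue layout of the requested class.

    The glandular fraction G/(G+F) is driven to the class target within
    ``config.fraction_tol`` by flipping Voronoi cells between fat and
    glandular; a target that remains unreachable after bounded retries is an
    explicit error.
    """
    if breast_class not in CLASSES:
        raise ValueError(f"unknown breast class {breast_class!r}")
    target = config.class_targets[breast_class]
    for _ in range(max_retries):
        layout = _sample_layout_once(breast_class, target, config, rng)
        if abs(layout.glandular_fraction - target) <= config.fraction_tol:
            return layout
    raise RuntimeError(
        f"could not reach glandular fraction {target:.2f} for class "
        f"{breast_class!r} within tolerance {config.fraction_tol}"
    )


def _sample_layout_once(breast_class: str, target: float,
                        config: GeneratorConfig,
                        rng: np.random.Generator) -> TissueLayout:
    size = config.image_size
    fg = _breast_outline(size, rng)

    # distance into the breast; skin is a thin peripheral band
    dist = ndimage.distance_transform_edt(fg)
    skin_w = rng.integers(2, 4)  # 2 or 3 px
    skin = fg & (dist <= skin_w)
    interior = fg & (dist > skin_w)

    # ligaments: skeletonized Voronoi edges of Poisson-sampled interior seeds,
    # kept clear of the periphery so the segmentation band rule is unambiguous
    lig_zone = dist > (skin_w + 4)
    int_coords = np.argwhere(interior)
    # density is defined at the reference 512-px frame so that the number of
    # ligament compartments (the allocation granularity) is size-independent
    eff_density = config.ligament_seed_density * (512.0 / size) ** 2
    n_seeds = max(24, rng.poisson(eff_density * len(int_coords)))
    seeds = int_coords[rng.choice(len(int_coords), size=min(n_seeds, len(int_coords)),
                                  replace=False)]
    tree = cKDTree(seeds)
    _, owner_flat = tree.query(int_coords, k=1)
    owner = np.full((size, size), -1, dtype=np.int32)
    owner[interior] = owner_flat

    edges = np.zeros_like(fg)
    o = owner
    edges[:-1, :] |= (o[:-1, :] != o[1:, :]) & (o[:-1, :] >= 0) & (o[1:, :] >= 0)
    edges[:, :-1] |= (o[:, :-1] != o[:, 1:]) & (o[:, :-1] >= 0) & (o[:, 1:] >= 0)
    edges &= lig_zone
    ligament = skeletonize(edges)

    # tessellation cells (ligaments removed) carry the fat/glandular identity
    cells, n_cells = ndimage.label(interior & ~ligament)
    if n_cells < 2:
        cells, n_cells = ndimage.label(interior)
    areas = ndimage.sum_labels(np.ones_like(cells), cells, index=np.arange(1, n_cells + 1))
    order = rng.permutation(n_cells)
    total = areas.sum()

    # heterogeneous layouts get extra spiculated glandular "bursts" later;
    # aim the cell allocation a little low to leave room for them
    cell_target = target - 0.04 if breast_class == "heterogeneous" else target
    glandular_cells = np.zeros(n_cells, dtype=bool)
    g_area = 0.0
    for idx in order:
        if g_area / total >= cell_target:
            break
        glandular_cells[idx] = True
        g_area += areas[idx]

    label_map = np.zeros((size, size), dtype=np.uint8)
    label_map[interior] = FAT
    g_mask = glandular_cells[cells - 1] & (cells > 0)
    label_map[g_mask] = GLANDULAR

    if breast_class == "heterogeneous":
        _add_bursts(label_map, interior & ~ligament, rng)

    label_map[skin] = SKIN
    label_map[ligament & interior] = LIGAMENT

    # fine adjustment: flip whole cells toward the target fraction
    label_map = _tune_fraction(label_map, cells, areas, target,
                               config.fraction_tol, rng)

    f = np.count_nonzero(label_map == FAT)
    g = np.count_nonzero(label_map == GLANDULAR)
    frac = g / (g + f) if (g + f) else 0.0
    if f == 0 or g == 0 or not skin.any() or not (ligament & interior).any():
        frac = -1.0  # force retry: some tissue absent
    return TissueLayout(label_map=label_map, breast_class=breast_class,
                        glandular_fraction=frac)


def _add_bursts(label_map: np.ndarray, allowed: np.ndarray,
                rng: np.random.Generator) -> None:
    """Stamp spiculated star-shaped glandular components (heterogeneous class)."""
    size = label_map.shape[0]
    coords = np.argwhere(allowed)
    if not len(coords):
        return
    n_bursts = rng.integers(3, 7)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_bursts):
        cy, cx = coords[rng.integers(len(coords))]
        r0 = rng.uniform(0.02, 0.04) * size
        n_rays = rng.integers(5, 9)
        phase = rng.uniform(0, 2 * math.pi)
        theta = np.arctan2(yy - cy, xx - cx)
        rad = np.hypot(yy - cy, xx - cx)
        spike = np.abs(np.sin(n_rays * (theta - phase) / 2.0)) ** 3
        star = rad <= r0 * (0.35 + 1.3 * spike)
        label_map[star & allowed] = GLANDULAR


def _tune_fraction(label_map: np.ndarray, cells: np.ndarray, areas: np.ndarray,
                   target: float, tol: float, rng: np.random.Generator) -> np.ndarray:
    """Flip random tessellation cells F<->G until the fraction is in band."""
    n_cells = len(areas)
    f = np.count_nonzero(label_map == FAT)
    g = np.count_nonzero(label_map == GLANDULAR)
    order = np.concatenate([rng.permutation(n_cells) + 1,
                            rng.permutation(n_cells) + 1])
    for cid in order:
        frac = g / (g + f) if (g + f) else 0.0
        if abs(frac - target) <= tol * 0.8:
            break
        mask = cells == cid
        if frac < target:
            flip = mask & (label_map == FAT)
            n = np.count_nonzero(flip)
            if n and (g + n) / (g + f) - target < target - frac:
                label_map[flip] = GLANDULAR
                g += n
                f -= n
        else:
            flip = mask & (label_map == GLANDULAR)
            n = np.count_nonzero(flip)
            if n and target - (g - n) / (g + f) < frac - target:
                label_map[flip] = FAT
                g -= n
                f += n
    return label_map


_QUANTILE_GRID = (np.arange(2 ** 16) + 0.5) / 2 ** 16


@functools.lru_cache(maxsize=32)
def _law_quantiles(law: TissueLaw) -> np.ndarray:
    return law.ppf(_QUANTILE_GRID)


def _textured_field(law: TissueLaw, shape: tuple[int, int], sigma: float,
                    rng: np.random.Generator) -> np.ndarray:
    """I.i.d. scaled-Beta field, Gaussian-smoothed, rank-restored to the law.

    Smoothing induces the prescribed short-range texture; the subsequent
    rank-based histogram transform maps the smoothed field back onto the
    exact affine-Beta marginal (quantiles on a 2^16 grid), so the pixel
    marginal is preserved while spatial correlation is retained.
    """
    field = law.rvs(shape, rng)
    if sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
        quantiles = _law_quantiles(law)
        flat = field.ravel()
        ranks = np.argsort(flat, kind="stable")
        out = np.empty_like(flat)
        # map ordered ranks onto ordered quantiles of the prescribed law
        qidx = np.floor(np.arange(flat.size) / flat.size * len(quantiles)).astype(np.int64)
        out[ranks] = quantiles[qidx]
        field = out.reshape(shape)
    return field


def assign_intensities(layout: TissueLayout, model: IntensityModel,
                       rng: np.random.Generator) -> np.ndarray:
    """Render a layout to an 8-bit grayscale image.

    Each tissue contributes an independently textured full-frame field masked
    to its own pixels; background is exactly zero.  Quantization happens once,
    after summation, by round-half-to-even with clipping.
    """
    shape = layout.label_map.shape
    out = np.zeros(shape, dtype=np.float64)
    for lbl in (FAT, GLANDULAR, SKIN, LIGAMENT):
        mask = layout.label_map == lbl
        if not mask.any():
            continue
        field = _textured_field(model.law(lbl), shape, model.sigma, rng)
        out[mask] = field[mask]
    hi = 2 ** model.bit_depth - 1
    return np.clip(np.rint(out), 0, hi).astype(np.uint8)


def _image_rng(seed: int, index: int) -> tuple[np.random.Generator, int]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    child_seed = int(ss.generate_state(1)[0]) % (2 ** 31)
    return np.random.Generator(np.random.PCG64(child_seed)), child_seed


def iter_ensemble(config: GeneratorConfig,
                  model: IntensityModel | None = None,
                  with_layouts: bool = False) -> Iterator[dict]:
    """Yield ensemble records (image + metadata) without touching disk.

    Class labels follow the largest-remainder prevalence allocation,
    interleaved deterministically so any prefix is approximately on-mix.
    """
    model = model or IntensityModel()
    counts = class_allocation(config.n_images, config.prevalence)
    classes: list[str] = []
    for cls, cnt in zip(CLASSES, counts):
        classes.extend([cls] * cnt)
    perm_rng = np.random.Generator(np.random.PCG64(config.seed % (2 ** 31)))
    classes = [classes[i] for i in perm_rng.permutation(len(classes))]

    for i, cls in enumerate(classes):
        rng, child_seed = _image_rng(config.seed, i)
        layout = sample_layout(cls, config, rng)
        image = assign_intensities(layout, model, rng)
        rec = {
            "index": i,
            "filename": f"img_{i:06d}.png",
            "class": cls,
            "glandular_fraction": layout.glandular_fraction,
            "seed": child_seed,
            "image": image,
        }
        if with_layouts:
            rec["layout"] = layout
        yield rec


def generate_ensemble(config: GeneratorConfig, out_dir: str,
                      model: IntensityModel | None = None) -> pd.DataFrame:
    """Write a seeded ensemble of lossless 8-bit PNGs plus a manifest CSV.

    Returns the manifest (``filename,class,glandular_fraction,seed``); the
    same config always reproduces byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in iter_ensemble(config, model):
        path = os.path.join(out_dir, rec["filename"])
        try:
            Image.fromarray(rec["image"], mode="L").save(path, optimize=True)
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed writing {path}: {exc}") from exc
        rows.append({k: rec[k] for k in
                     ("filename", "class", "glandular_fraction", "seed")})
    manifest = pd.DataFrame(rows, columns=["filename", "class",
                                           "glandular_fraction", "seed"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
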