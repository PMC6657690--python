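"""Synthetic fluorescence-style muscle cross-sections with groundtruth.

The generator emulates the failure modes that make real stained sections
hard to segment: holes in the stained borders, intra-fibre speckle noise of
uniform or clustered distribution, noisy interstitial gap regions, a
brightness step from image stitching, and intensity variation between
fibres.  Geometry is a Lloyd-relaxed Voronoi mosaic (one relaxation pass
gives convex-ish, size-varied cells resembling fibre cross-sections); walls
are rendered at a configurable width and intensity, and border holes are
erased wall segments recorded exactly in a wall registry, so the expected
reference clusters of a sample can be computed without running any
detector.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .classify import (
    CLASS_BIG_FIBRE,
    CLASS_BORDER,
    CLASS_GAP,
    CLASS_SMALL_FIBRE,
    STRUCTURE_4,
)
from .config import ValidationError

logger = logging.getLogger(__name__)

#: Wall-hole span as a multiple of border width.  Holes must survive both the
#: 3x3 single-iteration border dilation of the watershed stage and the 11x11
#: closing of the reference pipeline, otherwise they would not exercise
#: cluster separation at all; 5x a 3 px wall gives a 15 px span.
HOLE_SPAN_FACTOR = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cross-section."""

    height: int = 256
    width: int = 256
    n_fibres: int = 18
    border_width: int = 3
    border_intensity: int = 230
    border_hole_rate: float = 0.0
    fibre_intensity_range: Tuple[int, int] = (50, 130)
    speckle_sd: float = 0.0
    speckle_clumping: str = "uniform"
    gap_fraction: float = 0.08
    gap_noise_sd: float = 0.0
    stitch_step: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fibres < 1:
            raise ValidationError("n_fibres must be >= 1")
        if not 0.0 <= self.border_hole_rate <= 1.0:
            raise ValidationError("border_hole_rate must be in [0, 1]")
        for v in (self.border_intensity, *self.fibre_intensity_range):
            if not 0 <= v <= 255:
                raise ValidationError(f"intensity {v} outside [0, 255]")
        if self.speckle_clumping not in ("uniform", "clustered"):
            raise ValidationError("speckle_clumping must be 'uniform' or 'clustered'")
        if self.height * self.width < 400 * self.n_fibres:
            raise ValidationError(
                f"{self.n_fibres} fibres do not fit a "
                f"{self.height}x{self.width} image (need >= 400 px each)"
            )


@dataclass
class SyntheticSample:
    """A generated image with its groundtruth and defect registry."""

    image: np.ndarray
    groundtruth: np.ndarray
    wall_registry: List[Tuple[int, int, bool]]
    boundary_cell_ids: frozenset
    wall_mask: np.ndarray
    rendered_wall_mask: np.ndarray
    gap_mask: np.ndarray
    config: SyntheticConfig


def generate_cross_section(cfg: SyntheticConfig) -> SyntheticSample:
    """Render one synthetic cross-section (deterministic given cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    mosaic = _lloyd_mosaic(h, w, cfg.n_fibres, rng)

    # carve interstitial gap regions out of whole mosaic cells
    cell_ids = np.arange(1, cfg.n_fibres + 1)
    areas = np.bincount(mosaic.ravel(), minlength=cfg.n_fibres + 1)[1:]
    gap_cells: set[int] = set()
    if cfg.gap_fraction > 0:
        target = cfg.gap_fraction * h * w
        order = rng.permutation(cell_ids)
        acc = 0
        for cid in order:
            if acc >= target:
                break
            gap_cells.add(int(cid))
            acc += int(areas[cid - 1])
        if len(gap_cells) >= cfg.n_fibres:
            gap_cells.discard(int(order[0]))  # keep at least one fibre

    # geometric walls: pixels near an interface between two mosaic cells
    interface = np.zeros((h, w), dtype=bool)
    interface[1:, :] |= mosaic[1:, :] != mosaic[:-1, :]
    interface[:, 1:] |= mosaic[:, 1:] != mosaic[:, :-1]
    pad = max(0, (cfg.border_width - 1) // 2)
    wall_mask = (
        ndi.binary_dilation(interface, iterations=pad) if pad else interface.copy()
    )

    # registry of walls between pairs of fibre cells, and hole injection;
    # holes are only punched between two fully imaged cells: fibres touching
    # the image boundary are excluded from groundtruth-based evaluation, so
    # defects there would not be observable
    edge_cells = set(
        int(x)
        for x in np.unique(
            np.concatenate([mosaic[0, :], mosaic[-1, :], mosaic[:, 0], mosaic[:, -1]])
        )
    )
    pair_pixels = _interface_pairs(mosaic)
    rendered_wall = wall_mask.copy()
    registry: List[Tuple[int, int, bool]] = []
    hole_radius = (HOLE_SPAN_FACTOR * cfg.border_width) / 2.0
    for (a, b), pixels in sorted(pair_pixels.items()):
        if a in gap_cells or b in gap_cells:
            continue
        hole = False
        eligible = a not in edge_cells and b not in edge_cells
        if eligible and cfg.border_hole_rate > 0 and rng.random() < cfg.border_hole_rate:
            hole = _erase_hole(rendered_wall, pixels, hole_radius, rng)
        registry.append((a, b, hole))

    # intensities
    lo, hi = cfg.fibre_intensity_range
    base_by_cell = np.zeros(cfg.n_fibres + 1)
    base_by_cell[1:] = rng.uniform(lo, hi, size=cfg.n_fibres)
    for cid in gap_cells:
        base_by_cell[cid] = 8.0
    img = base_by_cell[mosaic]

    gap_mask = np.isin(mosaic, sorted(gap_cells)) if gap_cells else np.zeros(
        (h, w), dtype=bool
    )
    fibre_mask = ~gap_mask

    if cfg.speckle_sd > 0:
        if cfg.speckle_clumping == "uniform":
            img[fibre_mask] += rng.normal(0, cfg.speckle_sd, int(fibre_mask.sum()))
        else:
            # clustered: low-frequency noise thresholded into bright blobs,
            # emulating membrane-vesicle spots, plus a mild uniform floor
            noise_field = ndi.gaussian_filter(rng.normal(size=(h, w)), 3.0)
            blobs = noise_field > np.quantile(noise_field, 0.88)
            img[blobs & fibre_mask] += 3.0 * cfg.speckle_sd
            img[fibre_mask] += rng.normal(
                0, 0.5 * cfg.speckle_sd, int(fibre_mask.sum())
            )
    if cfg.gap_noise_sd > 0 and gap_mask.any():
        img[gap_mask] += rng.normal(0, cfg.gap_noise_sd, int(gap_mask.sum()))

    img[rendered_wall] = cfg.border_intensity
    if cfg.stitch_step:
        img[:, w // 2:] += cfg.stitch_step
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)

    # groundtruth: fibre-cell interiors separated by the full geometric wall
    gt_source = np.where(fibre_mask & ~wall_mask, mosaic, 0)
    groundtruth, id_map = _relabel_cells(gt_source)
    boundary = np.unique(
        np.concatenate(
            [groundtruth[0, :], groundtruth[-1, :],
             groundtruth[:, 0], groundtruth[:, -1]]
        )
    )
    registry_gt = [
        (id_map[a], id_map[b], hole)
        for a, b, hole in registry
        if a in id_map and b in id_map
    ]
    return SyntheticSample(
        image=image,
        groundtruth=groundtruth,
        wall_registry=registry_gt,
        boundary_cell_ids=frozenset(int(x) for x in boundary if x > 0),
        wall_mask=wall_mask,
        rendered_wall_mask=rendered_wall,
        gap_mask=gap_mask,
        config=cfg,
    )


#: Difficulty presets: the study conditions under which the pipelines are
#: compared.  'moderate' is the benchmark regime (border holes wide enough to
#: defeat simple morphology, mild speckle and gap noise); 'hard' adds
#: clustered speckle, more/denser holes, a stitching brightness step and
#: stronger noise; 'clean' has no defects at all.
PRESETS = {
    "clean": dict(
        border_hole_rate=0.0, speckle_sd=0.0, gap_noise_sd=0.0,
        stitch_step=0, border_intensity=255, fibre_intensity_range=(60, 110),
    ),
    "moderate": dict(
        height=320, width=320, n_fibres=28,
        border_hole_rate=0.25, speckle_sd=10.0, gap_noise_sd=6.0,
        stitch_step=0, border_intensity=230, fibre_intensity_range=(50, 130),
    ),
    "hard": dict(
        height=320, width=320, n_fibres=28,
        border_hole_rate=0.4, speckle_sd=18.0, speckle_clumping="clustered",
        gap_noise_sd=12.0, stitch_step=25, border_intensity=200,
        fibre_intensity_range=(40, 150), gap_fraction=0.12,
    ),
}


def generate_benchmark(set_size: int, preset: str = "moderate",
                       seed: int = 0) -> list[SyntheticSample]:
    """Deterministic suite of samples under a difficulty preset."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=set_size)
    return [
        generate_cross_section(SyntheticConfig(seed=int(s), **PRESETS[preset]))
        for s in child_seeds
    ]


def annotation_from_groundtruth(sample: SyntheticSample,
                                strokes_per_class: int = 5,
                                seed: int = 0) -> np.ndarray:
    """Sparse brush-style annotation map derived from the groundtruth.

    Short blob strokes are placed inside intact wall segments (class
    'border'), gap regions, and fibre interiors split at the median area
    into 'big fibre' and 'small fibre'.  A class with no eligible region is
    omitted with a warning.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    h, w = sample.image.shape
    ann = np.zeros((h, w), dtype=np.uint8)
    if strokes_per_class == 0:
        return ann
    gt = sample.groundtruth
    cell_ids = [int(c) for c in np.unique(gt) if c > 0]
    cell_areas = {c: int((gt == c).sum()) for c in cell_ids}
    median = float(np.median(list(cell_areas.values()))) if cell_ids else 0.0
    interiors = ndi.binary_erosion(gt > 0, structure=np.ones((3, 3)), iterations=2)
    regions = {
        CLASS_BORDER: sample.rendered_wall_mask,
        CLASS_GAP: sample.gap_mask & ~sample.rendered_wall_mask,
        CLASS_BIG_FIBRE: interiors
        & np.isin(gt, [c for c in cell_ids if cell_areas[c] >= median]),
        CLASS_SMALL_FIBRE: interiors
        & np.isin(gt, [c for c in cell_ids if cell_areas[c] < median]),
    }
    for cls, region in regions.items():
        coords = np.argwhere(region)
        if coords.shape[0] == 0:
            logger.warning("no eligible region for class %d; omitted", cls)
            continue
        for _ in range(strokes_per_class):
            r, c = coords[rng.integers(0, coords.shape[0])]
            rr, cc = np.ogrid[:h, :w]
            stroke = ((rr - r) ** 2 + (cc - c) ** 2 <= 9) & region
            ann[stroke] = cls
    return ann


def _lloyd_mosaic(h: int, w: int, n: int, rng: np.random.Generator
                  ) -> np.ndarray:
    """Nearest-site mosaic after one discrete Lloyd relaxation pass."""
    pts = np.column_stack(
        [rng.uniform(0, h, size=n), rng.uniform(0, w, size=n)]
    )
    rr, cc = np.mgrid[0:h, 0:w]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    for _ in range(2):  # assign, relax once, assign again
        _, assignment = cKDTree(pts).query(grid)
        lab = assignment.reshape(h, w)
        new_pts = pts.copy()
        for i in range(n):
            sel = grid[assignment == i]
            if sel.shape[0]:
                new_pts[i] = sel.mean(axis=0)
        pts = new_pts
    return (lab + 1).astype(np.int32)


def _interface_pairs(mosaic: np.ndarray) -> dict:
    """Map sorted cell-id pair -> array of interface pixel coordinates."""
    pairs: dict[tuple, list] = {}
    for axis in (0, 1):
        a = mosaic[:-1, :] if axis == 0 else mosaic[:, :-1]
        b = mosaic[1:, :] if axis == 0 else mosaic[:, 1:]
        diff = a != b
        coords = np.argwhere(diff)
        if axis == 0:
            ids = np.stack([mosaic[:-1, :][diff], mosaic[1:, :][diff]], axis=1)
        else:
            coords = coords.copy()
            ids = np.stack([mosaic[:, :-1][diff], mosaic[:, 1:][diff]], axis=1)
        for (r, c), (i, j) in zip(coords, ids):
            key = (int(min(i, j)), int(max(i, j)))
            pairs.setdefault(key, []).append((int(r), int(c)))
    return {k: np.array(v) for k, v in pairs.items()}


def _erase_hole(wall: np.ndarray, pixels: np.ndarray, radius: float,
                rng: np.random.Generator) -> bool:
    """Erase a wall segment around a mid-wall pixel; False if wall too short."""
    if pixels.shape[0] < 2 * radius:
        return False
    # pick the hole centre from the central third of the wall run so the
    # erased span stays clear of wall junctions
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    middle = order[len(order) // 3: max(len(order) // 3 + 1, 2 * len(order) // 3)]
    r, c = pixels[middle[rng.integers(0, len(middle))]]
    h, w = wall.shape
    rr, cc = np.ogrid[:h, :w]
    disc = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    wall[disc] = False
    return True


def _relabel_cells(source: np.ndarray) -> tuple[np.ndarray, dict]:
    """Compact cell labels to 1..K (raster order); return old->new mapping.

    Keeps, per original cell, only its largest 4-connected component so that
    every groundtruth cell is connected (slivers can appear where walls
    pinch a Voronoi cell).
    """
    out = np.zeros_like(source, dtype=np.int32)
    next_id = 1
    id_map: dict[int, int] = {}
    order = []
    for cid in np.unique(source):
        if cid == 0:
            continue
        comp, n = ndi.label(source == cid, structure=STRUCTURE_4)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        mask = comp == keep
        first = int(np.argmax(mask.ravel()))
        order.append((first, int(cid), mask))
    for first, cid, mask in sorted(order):
        out[mask] = next_id
        id_map[cid] = next_id
        next_id += 1
    return out, id_map
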