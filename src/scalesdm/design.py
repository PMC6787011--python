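"""Nested study-area replication, background sampling and fold splits.

The multi-scale design grids the full domain into small square blocks
(level 1) keeping those with enough presence records, buffers a random
subset of blocks into non-overlapping larger extents (level 2), treats the
region partition as level 3 ("mountain ranges") and the full domain as
level 4. Background locations are cell centers sampled uniformly from the
eligible (below an elevation ceiling) cells of an extent, falling back to
all eligible cells when fewer than requested exist. Presence points are
split into k folds that partition the data (each point tests exactly once);
an independent-splits variant draws k unconstrained 80/20 splits instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.model_selection import KFold

from .raster import Raster

logger = logging.getLogger(__name__)

__all__ = [
    "ExtentSpec",
    "FoldSplit",
    "grid_blocks",
    "buffer_nonoverlapping",
    "region_extents",
    "sample_background",
    "kfold_split",
    "points_in_rect",
]


@dataclass(frozen=True)
class ExtentSpec:
    """A rectangular study-area replicate in the nesting hierarchy."""

    level: int
    replicate_id: str
    rect: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)
    parent: str | None = None
    n_presence: int = 0

    def __post_init__(self):
        if not 1 <= self.level <= 4:
            raise ValueError("extent level must be 1..4")
        xmin, ymin, xmax, ymax = self.rect
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate extent rectangle {self.rect}")

    @property
    def area_km2(self) -> float:
        xmin, ymin, xmax, ymax = self.rect
        return (xmax - xmin) * (ymax - ymin) / 1e6

    def contains_rect(self, other: tuple) -> bool:
        xmin, ymin, xmax, ymax = self.rect
        oxmin, oymin, oxmax, oymax = other
        return xmin <= oxmin and ymin <= oymin and oxmax <= xmax and oymax <= ymax

    def as_dict(self) -> dict:
        d = asdict(self)
        d["area_km2"] = self.area_km2
        return d


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def points_in_rect(points: np.ndarray, rect) -> np.ndarray:
    """Boolean mask of points inside a half-open [xmin,xmax) x [ymin,ymax) rect."""
    pts = np.asarray(points, float).reshape(-1, 2)
    xmin, ymin, xmax, ymax = rect
    return (pts[:, 0] >= xmin) & (pts[:, 0] < xmax) & (pts[:, 1] >= ymin) & (pts[:, 1] < ymax)


def grid_blocks(domain_rect, presences, block_area_km2: float = 50.0,
                min_presence: int = 20) -> list[ExtentSpec]:
    """Tile the domain with square blocks; keep those rich enough in presences.

    Blocks are anchored at the domain's top-left corner; a block is retained
    when it contains at least ``min_presence`` presence points. Mirrors the
    level-1 replication rule (50 km^2 blocks, >= 20 presences).
    """
    xmin, ymin, xmax, ymax = domain_rect
    side = float(np.sqrt(block_area_km2 * 1e6))
    if side > (xmax - xmin) or side > (ymax - ymin):
        raise ValueError("block larger than the domain")
    pts = np.asarray(presences, float).reshape(-1, 2)
    out = []
    ncols = int((xmax - xmin) // side)
    nrows = int((ymax - ymin) // side)
    k = 0
    for i in range(nrows):
        for j in range(ncols):
            rect = (
                xmin + j * side,
                ymax - (i + 1) * side,
                xmin + (j + 1) * side,
                ymax - i * side,
            )
            n = int(points_in_rect(pts, rect).sum()) if pts.size else 0
            if n >= min_presence:
                out.append(ExtentSpec(level=1, replicate_id=f"L1-{k:03d}",
                                      rect=rect, n_presence=n))
                k += 1
    return out


def buffer_nonoverlapping(blocks, domain_rect, target_area_km2: float = 500.0,
                          n_target: int = 9, seed: int = 0) -> list[ExtentSpec]:
    """Expand randomly chosen blocks into non-overlapping larger extents.

    Each drawn block is buffered to a concentric square of the target area,
    clipped to the domain; a candidate is accepted only if it overlaps no
    previously accepted extent. Returns fewer than ``n_target`` with a
    warning when geometry forbids more. Each accepted extent records its
    seed block as nested child via ``parent`` back-reference on the block.
    """
    if not blocks:
        return []
    if target_area_km2 <= blocks[0].area_km2:
        raise ValueError("target area must exceed the block area")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    side = float(np.sqrt(target_area_km2 * 1e6))
    dxmin, dymin, dxmax, dymax = domain_rect
    accepted: list[ExtentSpec] = []
    for idx in order:
        if len(accepted) >= n_target:
            break
        b = blocks[idx]
        bxmin, bymin, bxmax, bymax = b.rect
        cx, cy = (bxmin + bxmax) / 2, (bymin + bymax) / 2
        half = side / 2
        # concentric square, shifted to stay inside the domain where possible
        xmin = np.clip(cx - half, dxmin, max(dxmin, dxmax - side))
        ymin = np.clip(cy - half, dymin, max(dymin, dymax - side))
        rect = (xmin, ymin, min(xmin + side, dxmax), min(ymin + side, dymax))
        if any(_rects_overlap(rect, a.rect) for a in accepted):
            continue
        accepted.append(ExtentSpec(level=2, replicate_id=f"L2-{len(accepted):03d}",
                                   rect=rect, parent=b.replicate_id,
                                   n_presence=b.n_presence))
    if len(accepted) < n_target:
        logger.warning("buffer_nonoverlapping: only %d of %d requested extents fit",
                       len(accepted), n_target)
    return accepted


def _rects_overlap(a, b) -> bool:
    axmin, aymin, axmax, aymax = a
    bxmin, bymin, bxmax, bymax = b
    return axmin < bxmax and bxmin < axmax and aymin < bymax and bymin < aymax


def region_extents(regions: Raster, level: int = 3) -> list[ExtentSpec]:
    """Bounding-rectangle extents of each region label (synthetic level 3)."""
    labels = np.unique(regions.values[regions.valid_mask()]).astype(int)
    out = []
    for lab in labels:
        rows, cols = np.where(regions.values == lab)
        rect = (
            regions.x0 + cols.min() * regions.cell,
            regions.y0 - (rows.max() + 1) * regions.cell,
            regions.x0 + (cols.max() + 1) * regions.cell,
            regions.y0 - rows.min() * regions.cell,
        )
        out.append(ExtentSpec(level=level, replicate_id=f"L{level}-{lab:03d}", rect=rect))
    return out


def full_domain_extent(template: Raster) -> ExtentSpec:
    return ExtentSpec(level=4, replicate_id="L4-000", rect=template.bounds)


def sample_background(extent: ExtentSpec, template: Raster, elevation: Raster,
                      n: int = 10000, max_elev: float = 3600.0,
                      seed: int = 0) -> np.ndarray:
    """Background cell centers inside an extent, masked by elevation.

    Eligible cells are non-nodata cells of the template whose center lies in
    the extent and whose elevation is below ``max_elev`` (no bamboo in
    alpine areas, so a species could not plausibly occur there). If at most
    ``n`` cells are eligible, all are returned; otherwise ``n`` distinct
    cells are drawn uniformly without replacement.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    X, Y = template.cell_centers()
    eligible = template.valid_mask() & elevation.valid_mask()
    eligible &= elevation.values < max_elev
    xmin, ymin, xmax, ymax = extent.rect
    eligible &= (X >= xmin) & (X < xmax) & (Y > ymin) & (Y <= ymax)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError(f"extent {extent.replicate_id}: no eligible background cells")
    if idx.size > n:
        idx = np.random.default_rng(seed).choice(idx, size=n, replace=False)
    return np.column_stack([X.ravel()[idx], Y.ravel()[idx]])


def kfold_split(n_points: int, k: int = 5, seed: int = 0,
                independent_splits: bool = False) -> list[FoldSplit]:
    """Split presence indices into k folds (default: a true partition).

    With ``independent_splits`` each fold is an unconstrained random 80/20
    split instead (the looser reading of "k random combinations").
    """
    if n_points < k:
        raise ValueError(f"need at least k={k} points, got {n_points}")
    rng = np.random.default_rng(seed)
    if independent_splits:
        out = []
        n_test = max(1, round(n_points / k))
        for i in range(k):
            perm = rng.permutation(n_points)
            out.append(FoldSplit(i + 1, np.sort(perm[n_test:]), np.sort(perm[:n_test])))
        return out
    kf = KFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    return [FoldSplit(i + 1, tr, te)
            for i, (tr, te) in enumerate(kf.split(np.arange(n_points)))]


def write_extents_json(extents, path) -> None:
    with open(path, "w") as fh:
        json.dump([e.as_dict() for e in extents], fh, indent=2)


def read_extents_json(path) -> list[ExtentSpec]:
    with open(path) as fh:
        raw = json.load(fh)
    return [ExtentSpec(level=d["level"], replicate_id=d["replicate_id"],
                       rect=tuple(d["rect"]), parent=d.get("parent"),
                       n_presence=d.get("n_presence", 0)) for d in raw]
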