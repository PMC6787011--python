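"""Regular-grid data model and deterministic raster transformations.

All coordinates are planar meters. Grids use a top-left origin: row 0 is the
northmost row, y decreases with increasing row index, and a point (x, y) falls
in column ``floor((x - x0)/cell)``, row ``floor((y0 - y)/cell)``; cells are
half-open ``[edge, edge + cell)``.

The :class:`Raster` container is the universal carrier for predictors,
suitability surfaces and masks. Transformations cover the change-of-support
operations needed to build a grain ladder from fine-resolution inputs:
block aggregation (mean/median), bilinear resampling, slope derivation,
Euclidean distance to vector features, presence-point rasterization and
PCA band reduction.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "Raster",
    "PredictorStack",
    "PresenceGrid",
    "GRAIN_LADDER_M",
    "VARIABLE_SET_MIN_GRAIN",
    "aggregate",
    "bilinear_resample",
    "slope_from_dem",
    "distance_raster",
    "rasterize_presence",
    "pca_reduce",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: Grain ladder: successive factor-2 aggregations from the native 30 m grain.
GRAIN_LADDER_M = (30, 60, 120, 240, 480, 960, 1920)

#: Smallest grain at which each variable set is defined: the phenology bands
#: exist from 240 m upward, the climate bands from 960 m upward.
VARIABLE_SET_MIN_GRAIN = {"base": 30, "base_pheno": 240, "base_pheno_clim": 960}


@dataclass(frozen=True)
class Raster:
    """Single-band regular grid.

    Parameters
    ----------
    values : ndarray
        2-D float array, row-major, row 0 = northmost.
    x0, y0 : float
        Real-world coordinates (m) of the grid's top-left corner.
    cell : float
        Cell edge length in meters (square cells).
    nodata : float or None
        Sentinel for missing cells; ``None`` means all cells valid.
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell: float = 30.0
    nodata: float | None = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not self.cell > 0:
            raise ValueError("cell size must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.x0,
            self.y0 - self.nrows * self.cell,
            self.x0 + self.ncols * self.cell,
            self.y0,
        )

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are neither nodata nor NaN."""
        m = ~np.isnan(self.values)
        if self.nodata is not None:
            m &= self.values != self.nodata
        return m

    def masked(self) -> np.ndarray:
        """Values with nodata replaced by NaN."""
        out = self.values.copy()
        out[~self.valid_mask()] = np.nan
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center-coordinate arrays matching ``values``."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of points (half-open cell convention)."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - np.asarray(y, float)) / self.cell).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def sample(self, x, y) -> np.ndarray:
        """Values at point coordinates (nearest cell; NaN outside/nodata)."""
        row, col = self.index_of(x, y)
        inside = self.contains(x, y)
        out = np.full(row.shape, np.nan)
        r, c = row[inside], col[inside]
        vals = self.masked()
        out[inside] = vals[r, c]
        return out

    def with_values(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, float))

    def crop(self, rect: tuple[float, float, float, float]) -> "Raster":
        """Sub-raster covering cells whose centers fall in (xmin, ymin, xmax, ymax)."""
        xmin, ymin, xmax, ymax = rect
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.cell
        cs = np.where((xs >= xmin) & (xs <= xmax))[0]
        rs = np.where((ys >= ymin) & (ys <= ymax))[0]
        if cs.size == 0 or rs.size == 0:
            raise ValueError(f"crop rectangle {rect} covers no cell centers")
        sub = self.values[rs[0] : rs[-1] + 1, cs[0] : cs[-1] + 1]
        return Raster(
            sub,
            x0=self.x0 + cs[0] * self.cell,
            y0=self.y0 - rs[0] * self.cell,
            cell=self.cell,
            nodata=self.nodata,
        )


@dataclass
class PredictorStack:
    """Named, grid-aligned rasters forming one variable set at one grain."""

    name: str
    layers: dict[str, Raster]
    grain: float

    def __post_init__(self):
        rasters = list(self.layers.values())
        if not rasters:
            raise ValueError("predictor stack needs at least one layer")
        ref = rasters[0]
        for k, r in self.layers.items():
            if (
                r.shape != ref.shape
                or r.x0 != ref.x0
                or r.y0 != ref.y0
                or r.cell != ref.cell
            ):
                raise ValueError(f"layer {k!r} is not aligned with the stack grid")

    @property
    def template(self) -> Raster:
        return next(iter(self.layers.values()))

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def subset(self, names) -> "PredictorStack":
        return PredictorStack(
            name=self.name, layers={n: self.layers[n] for n in names}, grain=self.grain
        )

    def crop(self, rect) -> "PredictorStack":
        return PredictorStack(
            name=self.name,
            layers={n: r.crop(rect) for n, r in self.layers.items()},
            grain=self.grain,
        )

    def aggregate(self, factor: int, stat: str = "mean") -> "PredictorStack":
        return PredictorStack(
            name=self.name,
            layers={n: aggregate(r, factor, stat) for n, r in self.layers.items()},
            grain=self.grain * factor,
        )

    def table(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_cells, n_vars) value matrix over jointly valid cells + flat index."""
        valid = np.ones(self.template.shape, bool)
        for r in self.layers.values():
            valid &= r.valid_mask()
        idx = np.flatnonzero(valid)
        cols = [r.values.ravel()[idx] for r in self.layers.values()]
        return np.column_stack(cols), idx

    def sample(self, x, y) -> np.ndarray:
        """(n_points, n_vars) matrix of layer values at point coordinates."""
        return np.column_stack([r.sample(x, y) for r in self.layers.values()])


@dataclass
class PresenceGrid:
    """Presence points binned onto a grid.

    ``prevalence`` is the number of presence cells divided by the total
    non-nodata cells of the template grid.
    """

    mask: Raster
    counts: Raster
    n_points: int
    n_cells: int
    prevalence: float


# ---------------------------------------------------------------------------
# transformations


def aggregate(r: Raster, factor: int, stat: str = "mean") -> Raster:
    """Coarsen a raster by an integer factor using a block statistic.

    Each output cell summarises a ``factor x factor`` block of input cells,
    ignoring nodata; blocks that are entirely nodata become nodata. Trailing
    rows/columns that do not fill a complete block are dropped, which keeps
    every block statistic an unbiased summary of a full block.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"aggregation factor must be a positive integer, got {factor}")
    factor = int(factor)
    nr, nc = r.shape
    if nr < factor or nc < factor:
        raise ValueError(f"raster {r.shape} smaller than one {factor}x{factor} block")
    if factor == 1:
        return r
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    br, bc = nr // factor, nc // factor
    vals = r.masked()[: br * factor, : bc * factor]
    blocks = vals.reshape(br, factor, bc, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(br, bc, factor * factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        agg = np.nanmean(blocks, axis=2) if stat == "mean" else np.nanmedian(blocks, axis=2)
    nodata = r.nodata if r.nodata is not None else np.nan
    out = np.where(np.isnan(agg), nodata, agg)
    return Raster(out, x0=r.x0, y0=r.y0, cell=r.cell * factor, nodata=r.nodata)


def bilinear_resample(r: Raster, target_cell: float) -> Raster:
    """Resample to a new cell size by bilinear interpolation of cell centers.

    The output grid covers the same footprint (rounded down to whole target
    cells); edge cells clamp to the nearest valid input centers, so the
    operation is exact for affine surfaces.
    """
    if not target_cell > 0:
        raise ValueError("target_cell must be positive")
    vals = r.masked()
    if np.all(np.isnan(vals)):
        raise ValueError("cannot resample an all-nodata raster")
    # fill nodata by nearest valid neighbor so interpolation never mixes in NaN
    nodata_mask = np.isnan(vals)
    if nodata_mask.any():
        from scipy.ndimage import distance_transform_edt

        _, (ri, ci) = distance_transform_edt(nodata_mask, return_indices=True)
        filled = vals[ri, ci]
    else:
        filled = vals
    nr = max(1, int(r.nrows * r.cell / target_cell))
    nc = max(1, int(r.ncols * r.cell / target_cell))
    # fractional row/col positions of output centers in input index space
    xs = (np.arange(nc) + 0.5) * target_cell
    ys = (np.arange(nr) + 0.5) * target_cell
    fc = np.clip(xs / r.cell - 0.5, 0, r.ncols - 1)
    fr = np.clip(ys / r.cell - 0.5, 0, r.nrows - 1)
    r0 = np.floor(fr).astype(int)
    c0 = np.floor(fc).astype(int)
    r1 = np.minimum(r0 + 1, r.nrows - 1)
    c1 = np.minimum(c0 + 1, r.ncols - 1)
    wr = (fr - r0)[:, None]
    wc = (fc - c0)[None, :]
    out = (
        filled[np.ix_(r0, c0)] * (1 - wr) * (1 - wc)
        + filled[np.ix_(r0, c1)] * (1 - wr) * wc
        + filled[np.ix_(r1, c0)] * wr * (1 - wc)
        + filled[np.ix_(r1, c1)] * wr * wc
    )
    if nodata_mask.any():
        # mark output cells whose own center falls in a nodata input cell
        src_r = np.clip(np.round(fr - 0.0).astype(int), 0, r.nrows - 1)
        src_c = np.clip(np.round(fc - 0.0).astype(int), 0, r.ncols - 1)
        bad = nodata_mask[np.ix_(src_r, src_c)]
        nodata = r.nodata if r.nodata is not None else np.nan
        out = np.where(bad, nodata, out)
    return Raster(out, x0=r.x0, y0=r.y0, cell=float(target_cell), nodata=r.nodata)


def slope_from_dem(dem: Raster) -> Raster:
    """Terrain slope in degrees from a DEM via Horn's 3x3 finite differences.

    Border cells use edge replication. Output lies in [0, 90).
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3")
    z = np.pad(dem.masked(), 1, mode="edge")
    # Horn (1981) weights: rate of change from the 8 neighbors
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * dem.cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * dem.cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    nodata = dem.nodata if dem.nodata is not None else np.nan
    slope = np.where(np.isnan(slope), nodata, slope)
    return Raster(slope, x0=dem.x0, y0=dem.y0, cell=dem.cell, nodata=dem.nodata)


def distance_raster(features, grid: Raster) -> Raster:
    """Euclidean distance (m) from each cell center to the nearest feature.

    ``features`` is an iterable of shapely geometries, (x, y) point tuples, or
    coordinate sequences (treated as polylines).
    """
    geoms = []
    for f in features:
        if hasattr(f, "distance"):
            geoms.append(f)
        else:
            arr = np.asarray(f, float)
            if arr.ndim == 1:
                geoms.append(Point(arr))
            else:
                geoms.append(LineString(arr) if len(arr) > 1 else Point(arr[0]))
    if not geoms:
        raise ValueError("distance_raster requires at least one feature")
    import shapely

    X, Y = grid.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    tree = STRtree(geoms)
    nearest = np.atleast_1d(tree.nearest(pts))
    geom_arr = np.array(geoms, dtype=object)
    dist = shapely.distance(pts, geom_arr[nearest])
    out = np.asarray(dist, float).reshape(grid.shape)
    if grid.nodata is not None:
        out = np.where(grid.valid_mask(), out, grid.nodata)
    return Raster(out, x0=grid.x0, y0=grid.y0, cell=grid.cell, nodata=grid.nodata)


def rasterize_presence(points, grid: Raster) -> PresenceGrid:
    """Bin presence points onto a template grid.

    Points outside the grid footprint are dropped with a logged warning.
    Prevalence is presence cells over the template's non-nodata cell count.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    counts = np.zeros(grid.shape, dtype=float)
    n_retained = 0
    if pts.size:
        inside = grid.contains(pts[:, 0], pts[:, 1])
        if not inside.all():
            logger.warning(
                "rasterize_presence: dropped %d point(s) outside the grid footprint",
                int((~inside).sum()),
            )
        pts = pts[inside]
        n_retained = len(pts)
        if n_retained:
            row, col = grid.index_of(pts[:, 0], pts[:, 1])
            np.add.at(counts, (row, col), 1.0)
    valid = grid.valid_mask()
    counts[~valid] = 0.0
    mask = (counts > 0).astype(float)
    n_cells = int(mask.sum())
    total = int(valid.sum())
    prevalence = n_cells / total if total else 0.0
    geo = dict(x0=grid.x0, y0=grid.y0, cell=grid.cell, nodata=None)
    return PresenceGrid(
        mask=Raster(mask, **geo),
        counts=Raster(counts, **geo),
        n_points=int(counts.sum()),
        n_cells=n_cells,
        prevalence=prevalence,
    )


def pca_reduce(
    stack: PredictorStack,
    variance_threshold: float = 0.99,
    max_components: int = 5,
    prefix: str = "pc",
) -> PredictorStack:
    """Reduce a correlated multiband stack to its leading principal components.

    Bands are centered and scaled to unit variance before decomposition
    (correlation-matrix PCA, since bands may mix units). Retains the minimal
    number of leading components whose cumulative explained variance reaches
    ``variance_threshold``, capped at ``max_components``. Constant bands are
    dropped with a warning.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    if len(stack.layers) < 2:
        raise ValueError("pca_reduce needs at least 2 bands")
    X, idx = stack.table()
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all bands are constant; PCA undefined")
    if not keep.all():
        dropped = [v for v, k in zip(stack.variables, keep) if not k]
        logger.warning("pca_reduce: dropping constant band(s) %s", dropped)
        X = X[:, keep]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, max_components, scores.shape[1])
    template = stack.template
    nodata = np.nan if template.nodata is None else template.nodata
    layers = {}
    for j in range(k):
        band = np.full(template.values.size, nodata)
        band[idx] = scores[:, j]
        layers[f"{prefix}{j + 1}"] = Raster(
            band.reshape(template.shape),
            x0=template.x0,
            y0=template.y0,
            cell=template.cell,
            nodata=template.nodata if template.nodata is not None else None,
        )
    return PredictorStack(name=f"{stack.name}_pca", layers=layers, grain=stack.grain)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(r: Raster, path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    nodata = r.nodata if r.nodata is not None else -9999.0
    vals = np.where(r.valid_mask(), r.values, nodata)
    yll = r.y0 - r.nrows * r.cell
    with open(path, "w") as fh:
        fh.write(f"ncols {r.ncols}\n")
        fh.write(f"nrows {r.nrows}\n")
        fh.write(f"xllcorner {_fmt(r.x0)}\n")
        fh.write(f"yllcorner {_fmt(yll)}\n")
        fh.write(f"cellsize {_fmt(r.cell)}\n")
        fh.write(f"NODATA_value {_fmt(nodata)}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc) into a :class:`Raster`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.asarray(rows, float)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared nrows/ncols")
    cell = header["cellsize"]
    return Raster(
        vals,
        x0=header["xllcorner"],
        y0=header["yllcorner"] + vals.shape[0] * cell,
        cell=cell,
        nodata=header.get("nodata_value"),
    )


def _fmt(v: float) -> str:
    return str(int(v)) if float(v) == int(v) else repr(float(v))
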