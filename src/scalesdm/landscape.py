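"""Synthetic landscapes with known habitat truth.

Real range-wide survey data for elusive species are often confidential, so
every downstream stage of the pipeline is exercised against generated
landscapes whose true suitability surface is known exactly. The generator
emulates the structure of the predictors a range-wide habitat study uses:

* spatially autocorrelated continuous fields (elevation-like, percent-forest
  in [0, 100]) built from exponential-covariance Gaussian random fields,
* distance-to-linear-feature rasters for roads and streams,
* an 11-band "phenology" stack mixed from a few latent fields so that many
  band pairs are highly correlated (|r| > 0.9), destined for PCA reduction,
* five coarse "climate" bands generated at a coarse grain and resampled,
* a region partition carrying optionally nonstationary response coefficients
  (different populations responding differently to the same predictors),
* survey-style presence sampling: Poisson detections per coarse survey cell
  with intensity proportional to mean suitability in the cell.

All outputs are bit-identical across runs for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .raster import (
    PredictorStack,
    Raster,
    bilinear_resample,
    distance_raster,
    slope_from_dem,
)

__all__ = [
    "TruthConfig",
    "SurveyDesign",
    "BASE_VARIABLES",
    "PHENO_VARIABLES",
    "CLIMATE_VARIABLES",
    "gaussian_field",
    "region_mask",
    "make_landscape",
    "true_suitability",
    "simulate_survey",
]

BASE_VARIABLES = ("elevation", "slope", "forest", "dist_road", "dist_stream")
PHENO_VARIABLES = tuple(f"pheno{i + 1}" for i in range(11))
CLIMATE_VARIABLES = (
    "temp_mean",
    "temp_seasonality",
    "temp_range",
    "precip_annual",
    "precip_seasonality",
)


def _default_coefficients() -> dict:
    # Mid-elevation optimum, strong positive forest response, avoidance of
    # roads (positive distance effect), mild slope and stream effects.
    return {
        0: {
            "elevation": (0.5, -1.0),
            "forest": (1.2, 0.0),
            "dist_road": (0.7, 0.0),
            "slope": (-0.5, 0.0),
            "dist_stream": (-0.3, 0.0),
        }
    }


@dataclass
class TruthConfig:
    """Ground-truth recipe for one synthetic landscape.

    ``coefficients`` maps region id -> variable -> (linear, quadratic)
    response on the standardized predictor; with ``n_regions == 1`` the truth
    is stationary. ``field_range`` sets the autocorrelation range (m) used
    for the main predictor fields.
    """

    shape: tuple[int, int] = (1000, 1000)
    cell: float = 30.0
    field_range: float = 3000.0
    coefficients: dict = field(default_factory=_default_coefficients)
    intercepts: dict = field(default_factory=lambda: {0: -2.0})
    n_regions: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        # broadcast a single region's coefficients to all regions
        for r in range(self.n_regions):
            if r not in self.coefficients:
                self.coefficients[r] = dict(self.coefficients[0])
            if r not in self.intercepts:
                self.intercepts[r] = self.intercepts[0]

    def to_record(self) -> dict:
        return {
            "shape": list(self.shape),
            "cell": self.cell,
            "field_range": self.field_range,
            "n_regions": self.n_regions,
            "seed": self.seed,
            "intercepts": {str(k): v for k, v in self.intercepts.items()},
            "coefficients": {
                str(r): {v: list(ab) for v, ab in cm.items()}
                for r, cm in self.coefficients.items()
            },
        }


@dataclass
class SurveyDesign:
    """Survey emulation: line-transect searches within coarse grid cells.

    ``transect_cell`` is the edge of the square survey cell in meters; the
    default 1414 m approximates a 2 km^2 survey cell. Expected detections in
    a surveyed cell equal ``detection_scale`` times the cell's mean true
    suitability.
    """

    transect_cell: float = 1414.0
    detection_scale: float = 12.0
    seed: int = 0


def gaussian_field(
    shape: tuple[int, int],
    cell: float,
    range_m: float,
    sill: float = 1.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> Raster:
    """Zero-mean Gaussian random field with exponential autocovariance.

    Uses circulant embedding (Dietrich & Newsam) on a doubled torus, so the
    marginal variance equals ``sill`` and the autocovariance is
    ``sill * exp(-h / range_m)`` up to the embedding approximation.
    ``range_m = 0`` degenerates to i.i.d. noise.
    """
    if range_m < 0:
        raise ValueError("range_m must be nonnegative")
    if not sill > 0:
        raise ValueError("sill must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    nr, nc = shape
    if range_m == 0:
        vals = rng.normal(0.0, np.sqrt(sill), size=(nr, nc))
        return Raster(vals, cell=cell, y0=nr * cell)
    m, n = 2 * nr, 2 * nc
    ii = np.minimum(np.arange(m), m - np.arange(m)) * cell
    jj = np.minimum(np.arange(n), n - np.arange(n)) * cell
    d = np.hypot(ii[:, None], jj[None, :])
    cov = sill * np.exp(-d / range_m)
    lam = np.fft.fft2(cov).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative embedding eigenvalues
    z = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
    f = np.fft.fft2(np.sqrt(lam / (m * n)) * z)
    vals = f.real[:nr, :nc]
    return Raster(vals, cell=cell, y0=nr * cell)


def region_mask(template: Raster, n_regions: int) -> Raster:
    """Partition the grid into contiguous blocks labelled 0..n_regions-1.

    A perfect-square count gives a quadrant-style grid; otherwise vertical
    strips. With one region the mask is constant 0.
    """
    nr, nc = template.shape
    labels = np.zeros((nr, nc), dtype=float)
    if n_regions > 1:
        k = int(round(np.sqrt(n_regions)))
        if k * k == n_regions:
            ri = np.minimum(np.arange(nr) * k // nr, k - 1)
            ci = np.minimum(np.arange(nc) * k // nc, k - 1)
            labels = (ri[:, None] * k + ci[None, :]).astype(float)
        else:
            ci = np.minimum(np.arange(nc) * n_regions // nc, n_regions - 1)
            labels = np.broadcast_to(ci[None, :], (nr, nc)).astype(float)
    return Raster(
        labels.copy(), x0=template.x0, y0=template.y0, cell=template.cell
    )


def _random_polyline(rng, bounds, n_vertices=6) -> np.ndarray:
    """A wiggly polyline spanning the domain between two random edge points."""
    xmin, ymin, xmax, ymax = bounds
    w, h = xmax - xmin, ymax - ymin
    if rng.random() < 0.5:  # left-to-right
        xs = np.linspace(xmin, xmax, n_vertices)
        ys = ymin + h * rng.random() + (h / 4) * rng.standard_normal(n_vertices)
    else:  # top-to-bottom
        ys = np.linspace(ymin, ymax, n_vertices)
        xs = xmin + w * rng.random() + (w / 4) * rng.standard_normal(n_vertices)
    return np.column_stack(
        [np.clip(xs, xmin, xmax), np.clip(ys, ymin, ymax)]
    )


def make_landscape(config: TruthConfig):
    """Generate the full predictor suite for one synthetic landscape.

    Returns ``(stack, regions, record)``: a 30 m-grain
    :class:`~scalesdm.raster.PredictorStack` holding the base variables, the
    11 phenology bands and the 5 climate bands; the region-label raster; and
    a JSON-ready truth record (config echo plus generation metadata).
    """
    nr, nc = config.shape
    if nr < 8 or nc < 8:
        raise ValueError("landscape too small to host the requested features")
    cell = config.cell
    rng = np.random.default_rng(config.seed)
    layers: dict[str, Raster] = {}

    # elevation: long-range field plus a gentle regional trend, mountainous scale
    elev_field = gaussian_field(config.shape, cell, config.field_range, rng=rng)
    trend = np.linspace(-1.0, 1.0, nc)[None, :] * 300.0
    elevation = 2600.0 + 700.0 * elev_field.values + trend
    layers["elevation"] = elev_field.with_values(elevation)
    layers["slope"] = slope_from_dem(layers["elevation"])

    # percent forest in [0, 100] via a logistic transform of its own field
    forest_field = gaussian_field(
        config.shape, cell, max(config.field_range / 2, cell), rng=rng
    )
    layers["forest"] = forest_field.with_values(
        np.clip(100.0 * expit(1.2 * forest_field.values + 0.4), 0.0, 100.0)
    )

    template = layers["elevation"]
    bounds = template.bounds
    roads = [_random_polyline(rng, bounds) for _ in range(3)]
    streams = [_random_polyline(rng, bounds) for _ in range(4)]
    layers["dist_road"] = distance_raster(roads, template)
    layers["dist_stream"] = distance_raster(streams, template)

    # phenology: 11 bands mixed from 3 latent fields with small noise so that
    # bands sharing a dominant latent correlate above 0.9
    latents = [
        gaussian_field(config.shape, cell, max(config.field_range / 3, cell), rng=rng)
        for _ in range(3)
    ]
    for j, name in enumerate(PHENO_VARIABLES):
        k = j % 3
        band = (
            latents[k].values
            + 0.15 * latents[(k + 1) % 3].values
            + 0.2 * rng.standard_normal(config.shape)
        )
        layers[name] = template.with_values(band)

    # climate: generated coarse (>= 960 m) then resampled down to the 30 m grid
    coarse_cell = 960.0
    coarse_shape = (
        max(2, int(np.ceil(nr * cell / coarse_cell))),
        max(2, int(np.ceil(nc * cell / coarse_cell))),
    )
    for name in CLIMATE_VARIABLES:
        coarse = gaussian_field(coarse_shape, coarse_cell, 10 * coarse_cell, rng=rng)
        fine = bilinear_resample(coarse, cell)
        vals = fine.values[:nr, :nc]
        if vals.shape != (nr, nc):  # pad the odd trailing row/col by edge copy
            vals = np.pad(
                vals, ((0, nr - vals.shape[0]), (0, nc - vals.shape[1])), mode="edge"
            )
        layers[name] = template.with_values(vals)

    stack = PredictorStack(name="landscape", layers=layers, grain=cell)
    regions = region_mask(template, config.n_regions)
    record = {
        "config": config.to_record(),
        "variables": list(layers),
        "n_roads": len(roads),
        "n_streams": len(streams),
    }
    return stack, regions, record


def true_suitability(
    stack: PredictorStack, config: TruthConfig, regions: Raster | None = None
) -> Raster:
    """True habitat suitability from the generating coefficients.

    Each predictor named in the coefficients is standardized over its valid
    cells, then suitability is ``expit(intercept_r + sum a*z + b*z^2)`` with
    region-specific coefficients.
    """
    template = stack.template
    if regions is None:
        regions = region_mask(template, config.n_regions)
    for cm in config.coefficients.values():
        for v in cm:
            if v not in stack.layers:
                raise KeyError(f"coefficient variable {v!r} missing from stack")
    variables = sorted({v for cm in config.coefficients.values() for v in cm})
    z = {}
    for v in variables:
        vals = stack.layers[v].masked()
        mu, sd = np.nanmean(vals), np.nanstd(vals)
        z[v] = (vals - mu) / (sd if sd > 0 else 1.0)
    eta = np.zeros(template.shape)
    labels = regions.values.astype(int)
    for r in range(config.n_regions):
        m = labels == r
        if not m.any():
            continue
        eta_r = np.full(template.shape, config.intercepts[r], dtype=float)
        for v, (a, b) in config.coefficients[r].items():
            eta_r += a * z[v] + b * z[v] ** 2
        eta[m] = eta_r[m]
    return template.with_values(expit(eta))


def simulate_survey(
    suitability: Raster, design: SurveyDesign, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate survey presence points; returns an (n, 2) array of (x, y).

    The landscape is tiled by square survey cells of ``design.transect_cell``
    anchored at the top-left corner. Detections in a cell are Poisson with
    mean ``detection_scale *`` (mean suitability over the cell's valid
    raster cells), each placed uniformly at random within the cell.
    """
    vals = suitability.masked()
    if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
        raise ValueError("suitability must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    step = int(max(1, round(design.transect_cell / suitability.cell)))
    nr, nc = suitability.shape
    xs, ys = [], []
    for r0 in range(0, nr, step):
        for c0 in range(0, nc, step):
            block = vals[r0 : r0 + step, c0 : c0 + step]
            mean_suit = np.nanmean(block) if np.any(~np.isnan(block)) else np.nan
            if not np.isfinite(mean_suit) or mean_suit <= 0:
                continue
            n = rng.poisson(design.detection_scale * mean_suit)
            if n == 0:
                continue
            x_lo = suitability.x0 + c0 * suitability.cell
            y_hi = suitability.y0 - r0 * suitability.cell
            w = min(step, nc - c0) * suitability.cell
            h = min(step, nr - r0) * suitability.cell
            xs.append(x_lo + w * rng.random(n))
            ys.append(y_hi - h * rng.random(n))
    if not xs:
        return np.empty((0, 2))
    return np.column_stack([np.concatenate(xs), np.concatenate(ys)])


def write_truth_record(record: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)


def write_points_csv(points: np.ndarray, path) -> None:
    """Write presence/background points as a two-column `x,y` CSV."""
    import pandas as pd

    pd.DataFrame(points, columns=["x", "y"]).to_csv(path, index=False)


def read_points_csv(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path)
    return df[["x", "y"]].to_numpy(float)
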