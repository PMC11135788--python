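"""Deterministic synthetic land-cover generation.

Real land-cover products cannot be redistributed with the package, so
every stage is exercised on synthetic rasters: tiny hand-checkable toys,
spatially autocorrelated landscapes with exact class proportions, and a
sprawl/infill-style conversion step that emulates two-date change.  All
generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import LandCoverRaster

__all__ = ["LandscapeParams", "toy_raster", "simulate_landscape", "simulate_change"]


TOY_NAMES = ("uniform_n", "stripes3", "checkerboard_ad", "holed7")


def toy_raster(name: str, pixel_size: float = 30.0) -> LandCoverRaster:
    """Small hand-checkable rasters.

    ``uniform_n``: 5x5 all natural.  ``stripes3``: 3x3 with rows of
    agriculture, natural, developed.  ``checkerboard_ad``: 8x8 alternating
    agriculture/developed.  ``holed7``: 7x7 natural with a nodata cross and
    a developed block, exercising nodata-excluding denominators.
    """
    if name == "uniform_n":
        grid = np.full((5, 5), 2, dtype=np.uint8)
    elif name == "stripes3":
        grid = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=np.uint8)
    elif name == "checkerboard_ad":
        idx = np.indices((8, 8)).sum(axis=0) % 2
        grid = np.where(idx == 0, 1, 3).astype(np.uint8)
    elif name == "holed7":
        grid = np.full((7, 7), 2, dtype=np.uint8)
        grid[3, :] = 0
        grid[:, 3] = 0
        grid[0:2, 0:2] = 3
    else:
        raise ValueError(f"unknown toy raster {name!r}; known: {TOY_NAMES}")
    return LandCoverRaster(grid, pixel_size)


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of the autocorrelated landscape generator.

    ``autocorr_length`` is the Gaussian smoothing length in pixels — the
    characteristic patch scale.  ``proportions`` are the target (a, n, d)
    shares of valid pixels, realized exactly (to the pixel) by rank
    thresholding.
    """

    rows: int = 200
    cols: int = 200
    proportions: tuple[float, float, float] = (0.2, 0.6, 0.2)
    nodata_fraction: float = 0.0
    autocorr_length: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("raster dimensions must be positive")
        p = self.proportions
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1) > 1e-9:
            raise ValueError("target proportions must be non-negative and sum to 1")
        if not (0 <= self.nodata_fraction < 1):
            raise ValueError("nodata fraction must lie in [0, 1)")
        if self.autocorr_length < 0:
            raise ValueError("autocorrelation length must be non-negative")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], length: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if length > 0:
        z = ndimage.gaussian_filter(z, sigma=length, mode="wrap")
    # rank-normalize so thresholds are quantiles regardless of the noise law
    return z + rng.random(shape) * 1e-9  # break exact ties deterministically


def simulate_landscape(params: LandscapeParams, pixel_size: float = 30.0) -> LandCoverRaster:
    """Seeded autocorrelated landscape hitting the target proportions exactly.

    Three independent smoothed Gaussian fields drive nodata placement,
    developed patches, and agriculture patches; class membership is decided
    by rank thresholds so realized proportions match the targets to the
    pixel regardless of the noise distribution.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.rows, params.cols)
    n_pix = params.rows * params.cols

    grid = np.full(shape, 2, dtype=np.uint8)

    n_nodata = int(round(params.nodata_fraction * n_pix))
    nodata_mask = np.zeros(shape, dtype=bool)
    if n_nodata:
        zn = _smooth_field(rng, shape, params.autocorr_length)
        thr = np.partition(zn.ravel(), n_pix - n_nodata)[n_pix - n_nodata]
        nodata_mask = zn >= thr
        # rank threshold can tie; trim deterministically to the exact count
        extra = int(nodata_mask.sum()) - n_nodata
        if extra > 0:
            idx = np.flatnonzero(nodata_mask.ravel())[:extra]
            nodata_mask.ravel()[idx] = False

    n_valid = n_pix - n_nodata
    pa, pn, pd = params.proportions
    n_dev = int(round(pd * n_valid))
    n_agr = int(round(pa * n_valid))
    if n_dev + n_agr > n_valid:
        raise ValueError("infeasible proportions with requested nodata fraction")

    zd = _smooth_field(rng, shape, params.autocorr_length)
    za = _smooth_field(rng, shape, params.autocorr_length)

    flat_valid = np.flatnonzero(~nodata_mask.ravel())
    order_d = flat_valid[np.argsort(zd.ravel()[flat_valid])[::-1]]
    dev_idx = order_d[:n_dev]
    grid.ravel()[dev_idx] = 3

    remaining = np.setdiff1d(flat_valid, dev_idx, assume_unique=True)
    order_a = remaining[np.argsort(za.ravel()[remaining])[::-1]]
    grid.ravel()[order_a[:n_agr]] = 1

    grid.ravel()[np.flatnonzero(nodata_mask.ravel())] = 0
    return LandCoverRaster(grid, pixel_size)


def simulate_change(
    raster: LandCoverRaster,
    conversion: float,
    seed: int = 0,
    neighbor_weight: float = 5.0,
) -> LandCoverRaster:
    """Convert a fraction of natural pixels to developed, preferring pixels
    adjacent to existing development (a sprawl/infill analogue).

    Exactly ``round(conversion * n_natural)`` pixels are converted.  Each
    natural pixel's sampling weight is ``1 + neighbor_weight * k`` where
    ``k`` is the number of developed pixels among its 8 neighbours, so
    conversion clusters around existing development but can also seed new
    patches.  Pure function of (raster, conversion, seed).
    """
    if not (0.0 <= conversion <= 1.0):
        raise ValueError("conversion rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = raster.data.copy()
    natural = np.flatnonzero(grid.ravel() == 2)
    n_convert = int(round(conversion * natural.size))
    if n_convert == 0:
        return LandCoverRaster(grid, raster.pixel_size, dict(raster.geotags))
    kernel = np.ones((3, 3)); kernel[1, 1] = 0
    dev_neighbors = ndimage.convolve(
        (grid == 3).astype(float), kernel, mode="constant"
    ).ravel()[natural]
    w = 1.0 + neighbor_weight * dev_neighbors
    chosen = rng.choice(natural, size=n_convert, replace=False, p=w / w.sum())
    grid.ravel()[chosen] = 3
    return LandCoverRaster(grid, raster.pixel_size, dict(raster.geotags))
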