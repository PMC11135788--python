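"""Moving-window composition and per-pixel mosaic classification.

The engine consumes a :class:`LandCoverRaster` — an 8-bit categorical grid
with codes ``{0 nodata, 1 agriculture, 2 natural, 3 developed}`` — and, for
each analysis scale (odd window side length), derives per-pixel window
proportions and the 19-class and 103-class mosaic rasters.

Window counts are computed exactly with integer summed-area tables; at map
edges the window shrinks to its intersection with the map, and nodata
pixels are excluded from the denominator.  A pixel whose own value is
nodata receives nodata output regardless of its neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .ternary import (
    CodeTable,
    DEFAULT_THRESHOLDS,
    LM19_CODES,
    LM19Label,
    Thresholds19,
)

__all__ = [
    "LandCoverRaster",
    "WindowSpec",
    "ProportionStack",
    "LMClassRaster",
    "ScaleProduct",
    "DEFAULT_WINDOWS",
    "window_proportions",
    "classify_raster",
    "window_area_hectares",
    "multiscale",
]

NODATA = 0
AGRICULTURE = 1
NATURAL = 2
DEVELOPED = 3

#: The five default analysis scales (window side lengths in pixels).
DEFAULT_WINDOWS: tuple[int, ...] = (7, 13, 27, 81, 243)


@dataclass
class LandCoverRaster:
    """Categorical land-cover grid: 0 nodata, 1 agriculture, 2 natural, 3 developed."""

    data: np.ndarray
    pixel_size: float = 30.0
    geotags: dict[int, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("land-cover raster must be a nonempty 2-D grid")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("land-cover raster must have an integer dtype")
        bad = np.setdiff1d(np.unique(self.data), [0, 1, 2, 3])
        if bad.size:
            raise ValueError(f"raster contains codes outside {{0,1,2,3}}: {bad.tolist()}")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        return self.data != NODATA


@dataclass(frozen=True)
class WindowSpec:
    """Square moving-window footprint; the side must be odd so it is centred."""

    side: int

    def __post_init__(self) -> None:
        if self.side < 3 or self.side % 2 == 0:
            raise ValueError(f"window side must be an odd integer >= 3, got {self.side}")

    @property
    def radius(self) -> int:
        return self.side // 2


def window_area_hectares(window: WindowSpec | int, pixel_size_m: float) -> float:
    """Ground area of a window footprint in hectares: ``(side * pixel)^2 / 1e4``."""
    side = window.side if isinstance(window, WindowSpec) else WindowSpec(window).side
    if pixel_size_m <= 0:
        raise ValueError("pixel size must be positive")
    return (side * pixel_size_m) ** 2 / 10_000.0


def _box_count(mask: np.ndarray, side: int) -> np.ndarray:
    """Exact count of True cells in the side x side window centred at each pixel,
    clipped to the grid (integer summed-area table)."""
    r = side // 2
    rows, cols = mask.shape
    sat = np.zeros((rows + 1, cols + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0, dtype=np.int64), axis=1, out=sat[1:, 1:])
    i = np.arange(rows)[:, None]
    j = np.arange(cols)[None, :]
    r0 = np.maximum(i - r, 0)
    r1 = np.minimum(i + r, rows - 1) + 1
    c0 = np.maximum(j - r, 0)
    c1 = np.minimum(j + r, cols - 1) + 1
    return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]


@dataclass
class ProportionStack:
    """Integer window counts per base type plus the valid-count denominator.

    Proportions are exposed as float views but all classification decisions
    (purity, decile indices, thresholds) are made on the integer counts.
    """

    count_a: np.ndarray
    count_n: np.ndarray
    count_d: np.ndarray
    total: np.ndarray
    center_valid: np.ndarray
    window: WindowSpec
    pixel_size: float = 30.0
    geotags: dict[int, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.total.shape

    def proportions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(a, n, d) proportion grids; NaN at nodata centres."""
        out = []
        with np.errstate(invalid="ignore", divide="ignore"):
            for c in (self.count_a, self.count_n, self.count_d):
                p = c / self.total
                p[~self.center_valid] = np.nan
                out.append(p)
        return tuple(out)


def window_proportions(raster: LandCoverRaster, window: WindowSpec | int) -> ProportionStack:
    """Window composition at every pixel of a land-cover raster.

    For each pixel with a valid (non-nodata) centre, counts base types in
    the centred ``side x side`` window intersected with the map, excluding
    nodata pixels, and records the valid-pixel denominator.
    """
    if isinstance(window, int):
        window = WindowSpec(window)
    rows, cols = raster.shape
    if window.side > rows and window.side > cols:
        raise ValueError(
            f"window side {window.side} exceeds both raster dimensions {raster.shape}"
        )
    g = raster.data
    counts = {cls: _box_count(g == cls, window.side) for cls in (1, 2, 3)}
    total = counts[1] + counts[2] + counts[3]
    return ProportionStack(
        count_a=counts[1],
        count_n=counts[2],
        count_d=counts[3],
        total=total,
        center_valid=g != NODATA,
        window=window,
        pixel_size=raster.pixel_size,
        geotags=dict(raster.geotags),
    )


@dataclass
class LMClassRaster:
    """Classified mosaic raster; ``dialect`` is '19' or '103'; 0 is nodata."""

    data: np.ndarray
    dialect: str
    window: WindowSpec
    codes: CodeTable | None = None
    thresholds: Thresholds19 = DEFAULT_THRESHOLDS
    pixel_size: float = 30.0
    geotags: dict[int, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dialect not in ("19", "103"):
            raise ValueError("dialect must be '19' or '103'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        return self.data != 0


def _lm19_category_lookup(thr: Thresholds19) -> np.ndarray:
    """Map (catA, catN, catD) component categories to canonical 19-class codes.

    Categories per component: 0 absent, 1 lowercase, 2 uppercase, 3 pure.
    """
    lut = np.zeros(64, dtype=np.uint8)
    letters = "and"
    for ca in range(4):
        for cn in range(4):
            for cd in range(4):
                cats = (ca, cn, cd)
                if cats.count(3) == 1 and cats.count(0) == 2:
                    pole = letters[cats.index(3)].upper()
                    name = pole + pole
                elif 3 not in cats and cats.count(2) <= 1:
                    upper = ""
                    lowers = []
                    for letter, cat in zip(letters, cats):
                        if cat == 2:
                            upper = letter.upper()
                        elif cat == 1:
                            lowers.append(letter)
                    name = upper + "".join(sorted(lowers))
                    if name not in LM19_CODES:
                        continue
                else:
                    continue
                lut[ca * 16 + cn * 4 + cd] = LM19_CODES[name]
    return lut


def _component_categories(
    count: np.ndarray, total: np.ndarray, thr: Thresholds19
) -> np.ndarray:
    """Exact per-pixel threshold category using rational comparisons on counts."""
    pres, dom = thr.as_fractions()
    cat = np.zeros(count.shape, dtype=np.uint8)
    # frac >= t  <=>  count * t.den >= t.num * total   (all int64, exact)
    ge_pres = count * pres.denominator >= pres.numerator * total
    ge_dom = count * dom.denominator >= dom.numerator * total
    pure = (count == total) & (total > 0)
    cat[ge_pres] = 1
    cat[ge_dom] = 2
    cat[pure] = 3
    return cat


def classify_raster(
    stack: ProportionStack,
    thr: Thresholds19 = DEFAULT_THRESHOLDS,
    codes: CodeTable | None = None,
) -> tuple[LMClassRaster, LMClassRaster]:
    """Per-pixel 19-class and 103-class mosaic rasters from window counts.

    Purity (the corner classes) is decided on integer counts
    (``count == total``), never on floating proportions; decile indices are
    ``(10 * count) // total``; grid-intersection compositions (indices
    summing to 10) are resolved exactly as in
    :func:`landmosaic.ternary.classify103`, so the scalar and raster paths
    agree pixel for pixel.
    """
    if codes is None:
        codes = CodeTable.canonical()
    ca, cn, cd = stack.count_a, stack.count_n, stack.count_d
    total = stack.total
    valid = stack.center_valid & (total > 0)

    # ---- 19-class --------------------------------------------------------
    lut19 = _lm19_category_lookup(thr)
    key = (
        _component_categories(ca, total, thr).astype(np.int32) * 16
        + _component_categories(cn, total, thr) * 4
        + _component_categories(cd, total, thr)
    )
    out19 = np.where(valid, lut19[key], 0).astype(np.uint8)

    # ---- 103-class -------------------------------------------------------
    safe_total = np.where(total > 0, total, 1)
    la = (10 * ca) // safe_total
    ln = (10 * cn) // safe_total
    ld = (10 * cd) // safe_total
    s = la + ln + ld
    grid = s == 10
    if grid.any():
        # decrement the largest component whose index is not a 19-region
        # boundary decile (1 or 6); ties broken d > a > n
        sa = np.where((la != 0) & (la != 1) & (la != 6), la, -1)
        sn = np.where((ln != 0) & (ln != 1) & (ln != 6), ln, -1)
        sd = np.where((ld != 0) & (ld != 1) & (ld != 6), ld, -1)
        d_pick = grid & (sd >= sa) & (sd >= sn)
        a_pick = grid & ~d_pick & (sa >= sn)
        n_pick = grid & ~d_pick & ~a_pick
        ld = ld - d_pick
        la = la - a_pick
        ln = ln - n_pick
        s = la + ln + ld
    la = np.clip(la, 0, 9).astype(np.intp)
    ln = np.clip(ln, 0, 9).astype(np.intp)

    up_lut = np.zeros((10, 10), dtype=np.uint8)
    down_lut = np.zeros((10, 10), dtype=np.uint8)
    for cell in codes:
        if cell.kind == "up":
            up_lut[cell.la, cell.ln] = codes.code_of(cell)
        elif cell.kind == "down":
            down_lut[cell.la, cell.ln] = codes.code_of(cell)

    out103 = np.zeros(total.shape, dtype=np.uint8)
    up_mask = valid & (s == 9)
    down_mask = valid & (s == 8)
    out103[up_mask] = up_lut[la[up_mask], ln[up_mask]]
    out103[down_mask] = down_lut[la[down_mask], ln[down_mask]]
    # corners override: purity on counts
    from .ternary import LMCell

    for pole, count in (("A", ca), ("N", cn), ("D", cd)):
        m = valid & (count == total)
        out103[m] = codes.code_of(LMCell.corner(pole))

    common = dict(
        window=stack.window,
        thresholds=thr,
        pixel_size=stack.pixel_size,
        geotags=dict(stack.geotags),
    )
    return (
        LMClassRaster(out19, "19", codes=None, **common),
        LMClassRaster(out103, "103", codes=codes, **common),
    )


@dataclass
class ScaleProduct:
    """Everything derived at one analysis scale."""

    window: WindowSpec
    area_ha: float
    stack: ProportionStack
    lm19: LMClassRaster
    lm103: LMClassRaster
    heatmap: "Any"  # landmosaic.heatmap.Heatmap


def multiscale(
    raster: LandCoverRaster,
    windows: Sequence[WindowSpec | int] = DEFAULT_WINDOWS,
    thr: Thresholds19 = DEFAULT_THRESHOLDS,
    codes: CodeTable | None = None,
) -> list[ScaleProduct]:
    """Run the full mosaic product set at each analysis scale.

    Returns one :class:`ScaleProduct` per window, ordered by window size.
    """
    from .heatmap import compute_heatmap

    specs = [w if isinstance(w, WindowSpec) else WindowSpec(w) for w in windows]
    if not specs:
        raise ValueError("at least one window size is required")
    sides = [w.side for w in specs]
    if len(set(sides)) != len(sides):
        raise ValueError(f"duplicate window sizes in {sides}")
    if codes is None:
        codes = CodeTable.canonical()

    products = []
    for w in sorted(specs, key=lambda w: w.side):
        stack = window_proportions(raster, w)
        lm19, lm103 = classify_raster(stack, thr, codes)
        products.append(
            ScaleProduct(
                window=w,
                area_ha=window_area_hectares(w, raster.pixel_size),
                stack=stack,
                lm19=lm19,
                lm103=lm103,
                heatmap=compute_heatmap(lm103),
            )
        )
    return products
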