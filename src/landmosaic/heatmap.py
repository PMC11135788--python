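"""The 103-bin heatmap summary and its change (delta) products.

A heatmap is the percent frequency distribution of a 103-class mosaic
raster's valid pixels over the chart cells; it is the scale- and
extent-normalized summary that makes maps of different dates or analysis
scales directly comparable.  Entries are kept at full precision — integer
rounding is presentation only — and always sum to 100.  A delta heatmap is
the cellwise difference of two heatmaps and sums to 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .ternary import CodeTable, LMCell, Thresholds19, DEFAULT_THRESHOLDS, cell_to_19, enumerate_cells

if TYPE_CHECKING:  # pragma: no cover
    from .raster import LMClassRaster
    from .reporting import SchemePartition

__all__ = [
    "Heatmap",
    "DeltaHeatmap",
    "GroupSummary",
    "compute_heatmap",
    "delta_heatmap",
    "group_summary",
    "heatmap_to_csv",
    "heatmap_from_csv",
    "plot_heatmap",
]

_TOL = 1e-6


@dataclass
class Heatmap:
    """Percent frequency per chart cell (canonical cell order), full precision."""

    percent: np.ndarray
    codes: CodeTable
    total_valid: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if self.percent.shape != (103,):
            raise ValueError("heatmap must have one entry per chart cell (103)")
        if (self.percent < -_TOL).any():
            raise ValueError("heatmap entries must be non-negative")
        if abs(self.percent.sum() - 100.0) > _TOL:
            raise ValueError(f"heatmap entries sum to {self.percent.sum()}, not 100")

    def __getitem__(self, cell: LMCell) -> float:
        return float(self.percent[_cell_index(cell)])

    def rounded(self) -> np.ndarray:
        """Integer display values (presentation only; never feeds computation)."""
        return np.rint(self.percent).astype(int)

    def max_cell(self) -> LMCell:
        return enumerate_cells()[int(np.argmax(self.percent))]


@dataclass
class DeltaHeatmap:
    """Signed percent change per chart cell between two heatmaps (sums to 0)."""

    percent: np.ndarray
    codes: CodeTable
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if self.percent.shape != (103,):
            raise ValueError("delta heatmap must have one entry per chart cell (103)")
        if abs(self.percent.sum()) > _TOL:
            raise ValueError(f"delta heatmap entries sum to {self.percent.sum()}, not 0")

    def __getitem__(self, cell: LMCell) -> float:
        return float(self.percent[_cell_index(cell)])

    def max_increase_cell(self) -> LMCell:
        return enumerate_cells()[int(np.argmax(self.percent))]

    def max_decrease_cell(self) -> LMCell:
        return enumerate_cells()[int(np.argmin(self.percent))]


@dataclass
class GroupSummary:
    """Per-group totals of a (delta) heatmap under a reporting partition."""

    labels: tuple[str, ...]
    totals: np.ndarray
    kind: str  # 'status' or 'delta'

    def as_dict(self) -> dict[str, float]:
        return {l: float(t) for l, t in zip(self.labels, self.totals)}

    def __getitem__(self, label: str) -> float:
        return float(self.totals[self.labels.index(label)])


_CELL_INDEX: dict[LMCell, int] | None = None


def _cell_index(cell: LMCell) -> int:
    global _CELL_INDEX
    if _CELL_INDEX is None:
        _CELL_INDEX = {c: i for i, c in enumerate(enumerate_cells())}
    return _CELL_INDEX[cell]


def compute_heatmap(lm103: "LMClassRaster") -> Heatmap:
    """Percent of valid pixels falling in each of the 103 chart cells."""
    if lm103.dialect != "103":
        raise ValueError("heatmap requires a 103-class mosaic raster")
    codes = lm103.codes or CodeTable.canonical()
    counts = np.bincount(lm103.data.ravel(), minlength=256)
    valid = int(counts[1:].sum())
    if valid == 0:
        raise ValueError("mosaic raster contains no valid pixels")
    unknown = [
        c for c in np.nonzero(counts)[0]
        if c != 0 and c not in codes._by_code
    ]
    if unknown:
        raise ValueError(f"raster codes {unknown} absent from the code table")
    percent = np.empty(103)
    for i, cell in enumerate(enumerate_cells()):
        percent[i] = 100.0 * counts[codes.code_of(cell)] / valid
    return Heatmap(
        percent,
        codes,
        valid,
        provenance={"window": lm103.window.side},
    )


def delta_heatmap(h1: Heatmap, h2: Heatmap) -> DeltaHeatmap:
    """Cellwise change ``h2 − h1`` between two heatmaps over the same code table."""
    if h1.codes.codes != h2.codes.codes:
        raise ValueError("heatmaps use different code tables")
    return DeltaHeatmap(
        h2.percent - h1.percent,
        h1.codes,
        provenance={"from": h1.provenance, "to": h2.provenance},
    )


def group_summary(
    h: Heatmap | DeltaHeatmap, part: "SchemePartition"
) -> GroupSummary:
    """Sum (delta) heatmap mass over the groups of a reporting partition."""
    cells = enumerate_cells()
    seen: set[int] = set()
    totals = []
    for group in part.groups:
        idx = [_cell_index(c) for c in group.cells]
        seen.update(idx)
        totals.append(h.percent[idx].sum())
    if len(seen) != len(cells):
        raise ValueError(
            f"partition {part.name!r} covers {len(seen)} of {len(cells)} cells"
        )
    kind = "status" if isinstance(h, Heatmap) else "delta"
    return GroupSummary(tuple(g.label for g in part.groups), np.array(totals), kind)


# ---------------------------------------------------------------------------
# CSV interchange (full precision; columns code,kind,la,ln,ld,percent)
# ---------------------------------------------------------------------------

def heatmap_to_csv(h: Heatmap | DeltaHeatmap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "kind", "la", "ln", "ld", "percent"])
        for i, cell in enumerate(enumerate_cells()):
            w.writerow(
                [h.codes.code_of(cell), cell.kind, cell.la, cell.ln, cell.ld,
                 repr(float(h.percent[i]))]
            )


def heatmap_from_csv(
    path: str | Path, codes: CodeTable | None = None
) -> Heatmap | DeltaHeatmap:
    """Read a heatmap (or delta heatmap, detected by its zero sum) from CSV."""
    if codes is None:
        codes = CodeTable.canonical()
    percent = np.full(103, np.nan)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"code", "kind", "la", "ln", "ld", "percent"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"heatmap CSV must have columns {sorted(required)}")
        for row in reader:
            cell = LMCell(row["kind"], int(row["la"]), int(row["ln"]), int(row["ld"]))
            if codes.code_of(cell) != int(row["code"]):
                raise ValueError(
                    f"cell {cell} carries code {row['code']}, expected {codes.code_of(cell)}"
                )
            i = _cell_index(cell)
            if not np.isnan(percent[i]):
                raise ValueError(f"duplicate row for cell {cell}")
            percent[i] = float(row["percent"])
    if np.isnan(percent).any():
        missing = int(np.isnan(percent).sum())
        raise ValueError(f"heatmap CSV missing {missing} cell rows")
    if abs(percent.sum()) < 50.0:  # delta heatmaps sum to 0, heatmaps to 100
        return DeltaHeatmap(percent, codes)
    return Heatmap(percent, codes, total_valid=0, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# Optional triangular rendering (same cell layout as the chart)
# ---------------------------------------------------------------------------

def _cell_polygon(cell: LMCell) -> np.ndarray:
    """Vertices of a chart cell in 2-D chart coordinates (N top, A left, D right)."""

    def to_xy(a: float, n: float, d: float) -> tuple[float, float]:
        return (d + 0.5 * n, n * np.sqrt(3) / 2)

    if cell.kind == "corner":
        c = {"A": (1, 0, 0), "N": (0, 1, 0), "D": (0, 0, 1)}[cell.pole]
        x, y = to_xy(*c)
        r = 0.02
        ang = np.linspace(0, 2 * np.pi, 16)
        return np.c_[x + r * np.cos(ang), y + r * np.sin(ang)]
    i, j, k = cell.la, cell.ln, cell.ld
    if cell.kind == "up":
        verts = [(i + 1, j, k), (i, j + 1, k), (i, j, k + 1)]
    else:
        verts = [(i + 1, j + 1, k), (i + 1, j, k + 1), (i, j + 1, k + 1)]
    return np.array([to_xy(a / 10, n / 10, d / 10) for a, n, d in verts])


def plot_heatmap(h: Heatmap | DeltaHeatmap, ax=None, annotate: bool = True):
    """Render the (delta) heatmap on the ternary chart layout.

    Returns the matplotlib Axes.  Cell shading follows the percent values;
    annotations show rounded integers as in the summary graphic.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6.5))
    vmax = max(abs(h.percent).max(), 1e-9)
    delta = isinstance(h, DeltaHeatmap)
    cmap = plt.get_cmap("coolwarm" if delta else "viridis")
    for i, cell in enumerate(enumerate_cells()):
        v = h.percent[i]
        frac = (v / vmax + 1) / 2 if delta else v / vmax
        poly = Polygon(
            _cell_polygon(cell), closed=True,
            facecolor=cmap(frac), edgecolor="0.6", linewidth=0.4,
        )
        ax.add_patch(poly)
        if annotate and round(v) != 0:
            x, y = _cell_polygon(cell).mean(axis=0)
            ax.text(x, y, f"{v:+.0f}" if delta else f"{v:.0f}",
                    ha="center", va="center", fontsize=6)
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 0.95)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.text(0.5, 0.9, "N", ha="center", fontsize=12)
    ax.text(-0.03, -0.03, "A", ha="center", fontsize=12)
    ax.text(1.03, -0.03, "D", ha="center", fontsize=12)
    return ax
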