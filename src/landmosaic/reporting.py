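"""Thematic reporting schemes over the 103-cell mosaic domain.

A reporting scheme partitions the ternary chart's 103 cells into a few
labeled groups and attaches display colors, so the same 103-class map can
be re-themed without re-running the moving-window analysis:

* ``background`` — dominant agriculture / natural / developed (one
  component at least 0.6) versus everything else (*mixed*);
* ``diversity`` — degree of heterogeneity: *uniform* (one component above
  0.85), *intermix* (all three near-equal), *triple* (all three present at
  0.1+), *dual* (the rest);
* ``refined_mixed`` — the background scheme with *mixed* subdivided into
  the central *adn2* and the three interface classes *dn2*, *an2*, *ad2*;
* ``intensity`` — cells binned by anthropic intensity.

Anthropic intensity maps the chart onto a normalized [0, 100]% scale of
human pressure: 0 at pure natural, 100 at pure developed, with agriculture
weighted half as heavily as development by default.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .ternary import (
    CodeTable,
    LMCell,
    cell_centroid,
    cell_to_19,
    enumerate_cells,
)

if TYPE_CHECKING:  # pragma: no cover
    from .raster import LMClassRaster

__all__ = [
    "PartitionGroup",
    "SchemePartition",
    "IntensityModel",
    "intensity_value",
    "build_partition",
    "apply_partition",
    "intensity_raster",
    "intensity_table_csv",
]


@dataclass(frozen=True)
class PartitionGroup:
    label: str
    cells: tuple[LMCell, ...]
    color: tuple[int, int, int]


@dataclass(frozen=True)
class SchemePartition:
    """Ordered, disjoint, covering grouping of the 103 chart cells."""

    name: str
    groups: tuple[PartitionGroup, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_cells = [c for g in self.groups for c in g.cells]
        if len(all_cells) != len(set(all_cells)):
            raise ValueError(f"partition {self.name!r} has overlapping groups")
        if set(all_cells) != set(enumerate_cells()):
            raise ValueError(
                f"partition {self.name!r} covers {len(set(all_cells))} of 103 cells"
            )

    def group_of(self, cell: LMCell) -> str:
        for g in self.groups:
            if cell in g.cells:
                return g.label
        raise KeyError(cell)  # pragma: no cover (covering enforced)

    def sizes(self) -> dict[str, int]:
        return {g.label: len(g.cells) for g in self.groups}

    def color_table(self) -> list[tuple[str, int, int, int]]:
        return [(g.label, *g.color) for g in self.groups]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "name": self.name,
            "params": self.params,
            "groups": [
                {
                    "label": g.label,
                    "color": list(g.color),
                    "cells": [[c.kind, c.la, c.ln, c.ld] for c in g.cells],
                }
                for g in self.groups
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SchemePartition":
        with open(path) as fh:
            obj = json.load(fh)
        groups = tuple(
            PartitionGroup(
                g["label"],
                tuple(LMCell(k, la, ln, ld) for k, la, ln, ld in g["cells"]),
                tuple(g["color"]),
            )
            for g in obj["groups"]
        )
        return cls(obj["name"], groups, obj.get("params", {}))


@dataclass(frozen=True)
class IntensityModel:
    """Linear anthropic-intensity model evaluated at cell centroids.

    ``intensity = 100 * (w_d * d + w_a * a)`` with defaults ``w_d = 1``,
    ``w_a = 0.5`` — the simple linear model anchored at 0 for pure natural,
    100 for pure developed, and 85 for the cell two decile steps from the
    developed corner along the developed–natural axis.  ``overrides`` maps
    individual cells to user intensities (e.g. to reproduce an external
    weighting table exactly); ``bin_edges`` define the display categories.
    """

    weight_developed: float = 1.0
    weight_agriculture: float = 0.5
    bin_edges: tuple[float, ...] = tuple(np.linspace(0.0, 100.0, 7))
    overrides: Mapping[LMCell, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in (self.weight_developed, self.weight_agriculture):
            if not (0.0 <= w <= 1.0):
                raise ValueError("intensity weights must lie in [0, 1]")
        edges = self.bin_edges
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] != 0.0 or edges[-1] != 100.0:
            raise ValueError("bin edges must span [0, 100]")
        known = set(enumerate_cells())
        bad = [c for c in self.overrides if c not in known]
        if bad:
            raise ValueError(f"override table references unknown cells: {bad}")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_of(self, value: float) -> int:
        """Category index of an intensity value; the last bin is closed."""
        return min(
            int(np.searchsorted(self.bin_edges, value, side="right") - 1),
            self.n_bins - 1,
        )


def intensity_value(cell: LMCell, model: IntensityModel = IntensityModel()) -> float:
    """Anthropic intensity of a chart cell in percent [0, 100]."""
    if cell in model.overrides:
        return float(model.overrides[cell])
    c = cell_centroid(cell)
    return 100.0 * (model.weight_developed * c.d + model.weight_agriculture * c.a)


# ---------------------------------------------------------------------------
# Built-in partitions
# ---------------------------------------------------------------------------

_BACKGROUND_COLORS = {
    "Ax": (70, 110, 230),   # agriculture-dominant: blue
    "Nx": (40, 150, 60),    # natural-dominant: green
    "Dx": (230, 120, 40),   # developed-dominant: orange
    "mixed": (150, 150, 150),
}
_DIVERSITY_COLORS = {
    "intermix": (220, 30, 30),
    "triple": (245, 150, 40),
    "dual": (150, 200, 235),
    "uniform": (25, 50, 140),
}
_REFINED_COLORS = {
    **{k: v for k, v in _BACKGROUND_COLORS.items() if k != "mixed"},
    "adn2": (130, 130, 130),
    "dn2": (170, 200, 120),
    "an2": (120, 180, 200),
    "ad2": (200, 140, 200),
}
_INTENSITY_COLORS = [
    (26, 110, 44), (140, 200, 90), (250, 230, 120),
    (245, 170, 70), (220, 90, 40), (140, 20, 20),
]


def _background_groups(dominance: float) -> dict[str, list[LMCell]]:
    groups: dict[str, list[LMCell]] = {"Ax": [], "Nx": [], "Dx": [], "mixed": []}
    for cell in enumerate_cells():
        c = cell_centroid(cell)
        if c.a >= dominance:
            groups["Ax"].append(cell)
        elif c.n >= dominance:
            groups["Nx"].append(cell)
        elif c.d >= dominance:
            groups["Dx"].append(cell)
        else:
            groups["mixed"].append(cell)
    return groups


def _refined_mixed_assign(cell: LMCell, lo: float) -> str:
    """Subdivide a mixed cell: adn2 if all components >= lo at the centroid,
    otherwise the interface class opposite the minimum component (tie a,d,n)."""
    c = cell_centroid(cell)
    if min(c.a, c.n, c.d) >= lo:
        return "adn2"
    comps = {"a": c.a, "d": c.d, "n": c.n}  # tie order a, d, n
    weakest = min(comps, key=lambda k: (comps[k], "adn".index(k) if k in "adn" else 0))
    return {"a": "dn2", "n": "ad2", "d": "an2"}[weakest]


def build_partition(scheme: str, **params) -> SchemePartition:
    """Construct a built-in reporting partition by name.

    Schemes: ``background`` (param ``dominance``, default 0.6),
    ``diversity`` (params ``uniform_min`` 0.85, ``intermix_lo`` 0.25,
    ``intermix_hi`` 0.40, ``presence`` 0.1), ``refined_mixed`` (params
    ``dominance`` 0.6, ``adn2_min`` 0.2), ``intensity`` (param ``model``).
    All predicates are evaluated at cell centroids so groups are aligned
    with whole cells.
    """
    cells = enumerate_cells()

    def check(name: str, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError(f"parameter {name}={v} must lie in (0, 1)")
        return v

    if scheme == "background":
        dom = check("dominance", params.pop("dominance", 0.6))
        _no_extra(params)
        raw = _background_groups(dom)
        groups = tuple(
            PartitionGroup(lbl, tuple(raw[lbl]), _BACKGROUND_COLORS[lbl])
            for lbl in ("Ax", "Nx", "Dx", "mixed")
        )
        return SchemePartition("background", groups, {"dominance": dom})

    if scheme == "diversity":
        uniform_min = check("uniform_min", params.pop("uniform_min", 0.85))
        lo = check("intermix_lo", params.pop("intermix_lo", 0.25))
        hi = check("intermix_hi", params.pop("intermix_hi", 0.40))
        presence = check("presence", params.pop("presence", 0.1))
        _no_extra(params)
        raw: dict[str, list[LMCell]] = {
            "intermix": [], "triple": [], "dual": [], "uniform": []
        }
        for cell in cells:
            c = cell_centroid(cell)
            mx, mn = max(c.as_tuple()), min(c.as_tuple())
            if mx > uniform_min:
                raw["uniform"].append(cell)
            elif mn >= lo and mx < hi:
                raw["intermix"].append(cell)
            elif mn >= presence:
                raw["triple"].append(cell)
            else:
                raw["dual"].append(cell)
        groups = tuple(
            PartitionGroup(lbl, tuple(raw[lbl]), _DIVERSITY_COLORS[lbl])
            for lbl in ("intermix", "triple", "dual", "uniform")
        )
        return SchemePartition(
            "diversity", groups,
            {"uniform_min": uniform_min, "intermix_lo": lo,
             "intermix_hi": hi, "presence": presence},
        )

    if scheme == "refined_mixed":
        dom = check("dominance", params.pop("dominance", 0.6))
        adn2_min = check("adn2_min", params.pop("adn2_min", 0.2))
        _no_extra(params)
        bg = _background_groups(dom)
        raw = {"Ax": bg["Ax"], "Nx": bg["Nx"], "Dx": bg["Dx"],
               "adn2": [], "dn2": [], "an2": [], "ad2": []}
        for cell in bg["mixed"]:
            raw[_refined_mixed_assign(cell, adn2_min)].append(cell)
        groups = tuple(
            PartitionGroup(lbl, tuple(raw[lbl]), _REFINED_COLORS[lbl])
            for lbl in ("Ax", "Nx", "Dx", "adn2", "dn2", "an2", "ad2")
        )
        return SchemePartition(
            "refined_mixed", groups, {"dominance": dom, "adn2_min": adn2_min}
        )

    if scheme == "intensity":
        model = params.pop("model", IntensityModel())
        _no_extra(params)
        raw_bins: list[list[LMCell]] = [[] for _ in range(model.n_bins)]
        for cell in cells:
            raw_bins[model.bin_of(intensity_value(cell, model))].append(cell)
        colors = _INTENSITY_COLORS if model.n_bins == 6 else [
            tuple(int(255 * x) for x in (i / max(model.n_bins - 1, 1),) * 3)
            for i in range(model.n_bins)
        ]
        groups = tuple(
            PartitionGroup(
                f"[{model.bin_edges[i]:.1f},{model.bin_edges[i+1]:.1f}"
                + ("]" if i == model.n_bins - 1 else ")"),
                tuple(raw_bins[i]),
                tuple(colors[i]),
            )
            for i in range(model.n_bins)
        )
        return SchemePartition(
            "intensity", groups,
            {"weight_developed": model.weight_developed,
             "weight_agriculture": model.weight_agriculture,
             "bin_edges": list(model.bin_edges)},
        )

    raise ValueError(f"unknown reporting scheme {scheme!r}")


def _no_extra(params: dict) -> None:
    if params:
        raise ValueError(f"unknown parameters: {sorted(params)}")


# ---------------------------------------------------------------------------
# Application to rasters
# ---------------------------------------------------------------------------

def apply_partition(
    lm103: "LMClassRaster", part: SchemePartition
) -> tuple[np.ndarray, list[tuple[str, int, int, int]]]:
    """Per-pixel group labels (1-based group index; 0 = nodata) and the
    partition's color table."""
    if lm103.dialect != "103":
        raise ValueError("apply_partition requires a 103-class mosaic raster")
    codes = lm103.codes or CodeTable.canonical()
    lut = np.zeros(256, dtype=np.uint8)
    for gi, group in enumerate(part.groups, start=1):
        for cell in group.cells:
            lut[codes.code_of(cell)] = gi
    present = np.unique(lm103.data)
    bad = [int(c) for c in present if c != 0 and lut[c] == 0]
    if bad:
        raise ValueError(f"raster codes {bad} not covered by partition code table")
    return lut[lm103.data], part.color_table()


def intensity_raster(
    lm103: "LMClassRaster", model: IntensityModel = IntensityModel()
) -> np.ndarray:
    """Per-pixel anthropic intensity in [0, 100]; NaN at nodata pixels."""
    if lm103.dialect != "103":
        raise ValueError("intensity_raster requires a 103-class mosaic raster")
    codes = lm103.codes or CodeTable.canonical()
    lut = np.full(256, np.nan)
    for cell in enumerate_cells():
        lut[codes.code_of(cell)] = intensity_value(cell, model)
    return lut[lm103.data]


def intensity_table_csv(
    path: str | Path,
    model: IntensityModel = IntensityModel(),
    codes: CodeTable | None = None,
) -> None:
    """Export the 103-class → intensity recoding table (code, intensity, bin)."""
    if codes is None:
        codes = CodeTable.canonical()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "kind", "la", "ln", "ld", "intensity", "category"])
        for cell in enumerate_cells():
            v = intensity_value(cell, model)
            w.writerow(
                [codes.code_of(cell), cell.kind, cell.la, cell.ln, cell.ld,
                 repr(float(v)), model.bin_of(v)]
            )


def color_table_csv(part: SchemePartition, path: str | Path) -> None:
    """Export a partition's display colors as label,R,G,B."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "R", "G", "B"])
        for label, r, g, b in part.color_table():
            w.writerow([label, r, g, b])
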