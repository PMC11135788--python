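"""Recode arbitrary land-cover legends to the three mosaic base types.

The engine itself only knows codes ``{0 nodata, 1 agriculture, 2 natural,
3 developed}``; what those base types mean (and which source classes feed
them) is the user's choice.  A bundled default implements the standard
NLCD rule: classes 81 and 82 (pasture/hay, cultivated crops) become
agriculture, 21–24 (the four developed classes) become developed, 0 stays
nodata, and every other class is treated as natural.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .raster import LandCoverRaster
from .ternary import TernaryComposition

__all__ = ["RecodeTable", "nlcd_default_table", "apply_recode", "map_composition"]

_POLICIES = ("natural", "nodata", "error")


@dataclass(frozen=True)
class RecodeTable:
    """Mapping from source legend codes to base-type codes {0,1,2,3}.

    ``default_policy`` governs codes absent from the mapping: treat them
    as natural, as nodata, or raise.
    """

    mapping: dict[int, int]
    default_policy: str = "error"

    def __post_init__(self) -> None:
        if self.default_policy not in _POLICIES:
            raise ValueError(f"policy must be one of {_POLICIES}")
        for src, tgt in self.mapping.items():
            if tgt not in (0, 1, 2, 3):
                raise ValueError(f"target code {tgt} for source {src} not in {{0,1,2,3}}")
            if not (0 <= int(src) <= 255):
                raise ValueError(f"source code {src} outside 8-bit range")

    # -- interchange -------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target"])
            for src in sorted(self.mapping):
                w.writerow([src, self.mapping[src]])

    @classmethod
    def from_csv(cls, path: str | Path, default_policy: str = "error") -> "RecodeTable":
        mapping: dict[int, int] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"source", "target"} <= set(reader.fieldnames):
                raise ValueError("recode CSV must have columns source,target")
            for row in reader:
                mapping[int(row["source"])] = int(row["target"])
        return cls(mapping, default_policy)

    @classmethod
    def from_json(cls, path: str | Path) -> "RecodeTable":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            {int(k): int(v) for k, v in obj["mapping"].items()},
            obj.get("default_policy", "error"),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mapping": {str(k): v for k, v in sorted(self.mapping.items())},
                    "default_policy": self.default_policy,
                },
                fh,
                indent=2,
            )


def nlcd_default_table() -> RecodeTable:
    """The standard NLCD-to-mosaic rule: 81,82→agriculture; 21–24→developed;
    0→nodata; all other classes→natural."""
    mapping = {81: 1, 82: 1, 21: 3, 22: 3, 23: 3, 24: 3, 0: 0}
    return RecodeTable(mapping, default_policy="natural")


def apply_recode(raster: np.ndarray | LandCoverRaster, table: RecodeTable,
                 pixel_size: float = 30.0, geotags: dict | None = None) -> LandCoverRaster:
    """Elementwise legend substitution producing a valid base-type raster."""
    if isinstance(raster, LandCoverRaster):
        grid = raster.data
        pixel_size = raster.pixel_size
        geotags = dict(raster.geotags)
    else:
        grid = np.asarray(raster)
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError("source raster must be integer-typed")
    present = np.unique(grid)
    unlisted = [int(c) for c in present if int(c) not in table.mapping]
    if unlisted and table.default_policy == "error":
        raise ValueError(f"source codes {unlisted} not in recode table (policy=error)")
    default = 2 if table.default_policy == "natural" else 0
    lut = np.full(256, default, dtype=np.uint8)
    for src, tgt in table.mapping.items():
        lut[src] = tgt
    return LandCoverRaster(lut[grid.astype(np.uint8)], pixel_size, geotags or {})


def map_composition(raster: LandCoverRaster) -> tuple[TernaryComposition, float]:
    """Whole-map base-type composition over valid pixels, plus the nodata fraction."""
    counts = np.bincount(raster.data.ravel(), minlength=4)
    valid = int(counts[1] + counts[2] + counts[3])
    if valid == 0:
        raise ValueError("raster contains no valid pixels")
    comp = TernaryComposition(counts[1] / valid, counts[2] / valid, counts[3] / valid)
    return comp, float(counts[0] / raster.data.size)
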