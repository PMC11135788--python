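"""Temporal change products at the anthropic-intensity level.

Given intensity rasters for two dates (same extent, same intensity model),
the change map is the per-pixel signed difference in [-100, 100].  Change
statistics separate unchanged pixels (exactly zero difference — cell-level
identity under the default rational per-cell intensities) from changed
ones and histogram the changed pixels at integer resolution, optionally
grouped into display classes for the change-map legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ChangeStats", "intensity_change", "change_stats"]


def intensity_change(
    i1: np.ndarray, i2: np.ndarray, tolerance: float = 0.0
) -> np.ndarray:
    """Signed per-pixel intensity change ``i2 − i1``; NaN where either is NaN.

    ``tolerance`` zeroes differences with absolute value at or below it
    (useful with continuous override models); the default keeps exact
    cell-level identity as the no-change criterion.
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if i1.shape != i2.shape:
        raise ValueError(f"intensity rasters differ in shape: {i1.shape} vs {i2.shape}")
    delta = i2 - i1
    if tolerance > 0:
        delta[np.abs(delta) <= tolerance] = 0.0
    return delta


@dataclass
class ChangeStats:
    """Summary of an intensity-change raster.

    ``histogram`` counts changed pixels in integer-resolution bins centred
    on -100..100 (the zero bin is empty by construction); percentages are
    over valid pixels.
    """

    percent_unchanged: float
    percent_changed: float
    histogram: np.ndarray          # length 201, bins centred on -100..100
    n_valid: int
    n_changed: int
    display_groups: list[tuple[float, float, str, int]] = field(default_factory=list)
    # (lo, hi, label, count); intervals [lo, hi) except the last, [lo, hi]

    @property
    def bin_centers(self) -> np.ndarray:
        return np.arange(-100, 101)

    def as_dict(self) -> dict:
        return {
            "percent_unchanged": self.percent_unchanged,
            "percent_changed": self.percent_changed,
            "n_valid": self.n_valid,
            "n_changed": self.n_changed,
            "display_groups": [
                {"lo": lo, "hi": hi, "label": label, "count": count}
                for lo, hi, label, count in self.display_groups
            ],
        }


def change_stats(
    delta: np.ndarray,
    grouping: Sequence[tuple[float, float, str]] | None = None,
) -> ChangeStats:
    """Percent unchanged/changed and the changed-pixel histogram.

    ``grouping`` optionally bins the changed pixels into labeled display
    classes ``(lo, hi, label)``; the intervals must tile [-100, 100].
    """
    delta = np.asarray(delta, dtype=float)
    valid = ~np.isnan(delta)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("change raster contains no valid pixels")
    vals = delta[valid]
    changed = vals != 0.0
    n_changed = int(changed.sum())
    cvals = vals[changed]

    hist = np.zeros(201, dtype=np.int64)
    if n_changed:
        idx = np.clip(np.rint(cvals).astype(int) + 100, 0, 200)
        np.add.at(hist, idx, 1)

    groups: list[tuple[float, float, str, int]] = []
    if grouping is not None:
        edges = sorted(grouping, key=lambda g: g[0])
        if edges[0][0] > -100 or edges[-1][1] < 100 or any(
            abs(a[1] - b[0]) > 1e-9 for a, b in zip(edges, edges[1:])
        ):
            raise ValueError("display grouping must tile [-100, 100]")
        for i, (lo, hi, label) in enumerate(edges):
            last = i == len(edges) - 1
            sel = (cvals >= lo) & ((cvals <= hi) if last else (cvals < hi))
            groups.append((lo, hi, label, int(sel.sum())))

    return ChangeStats(
        percent_unchanged=100.0 * (n_valid - n_changed) / n_valid,
        percent_changed=100.0 * n_changed / n_valid,
        histogram=hist,
        n_valid=n_valid,
        n_changed=n_changed,
        display_groups=groups,
    )
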