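"""End-to-end product pipeline: recode → multi-scale mosaic → summaries.

Given one land-cover raster (or two dates), each analysis scale yields the
19-class and 103-class mosaic GeoTIFFs, the heatmap CSV (plus an optional
graphic), and the intensity map; with two dates also the delta heatmap,
the intensity-change raster, and change statistics.  The resolved
configuration and a JSON run summary are written alongside the products so
a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as rio
from .change import change_stats, intensity_change
from .heatmap import compute_heatmap, delta_heatmap, group_summary, heatmap_to_csv, plot_heatmap
from .raster import DEFAULT_WINDOWS, LandCoverRaster, multiscale, window_area_hectares
from .recode import RecodeTable, apply_recode, map_composition, nlcd_default_table
from .reporting import IntensityModel, apply_partition, build_partition, intensity_raster
from .ternary import CodeTable, Thresholds19

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("landmosaic")

CHANGE_NODATA = -32768


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    inputs: list[str]
    output_dir: str
    recode_table: str | None = "nlcd-default"   # path, 'nlcd-default', or None (pre-recoded)
    recode_policy: str = "natural"
    windows: Sequence[int] = DEFAULT_WINDOWS
    presence: float = 0.1
    dominance: float = 0.6
    code_table: str | None = None               # CSV path or None for canonical
    schemes: Sequence[str] = ("background",)
    weight_developed: float = 1.0
    weight_agriculture: float = 0.5
    plot: bool = False
    pixel_size: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.inputs) <= 2:
            raise ValueError("pipeline takes one raster or a two-date pair")
        self.windows = tuple(int(w) for w in self.windows)
        self.thresholds()  # validate
        self.intensity_model()

    def thresholds(self) -> Thresholds19:
        return Thresholds19(self.presence, self.dominance)

    def codes(self) -> CodeTable:
        if self.code_table:
            return CodeTable.from_csv(self.code_table)
        return CodeTable.canonical()

    def recode(self) -> RecodeTable | None:
        if self.recode_table is None:
            return None
        if self.recode_table == "nlcd-default":
            return nlcd_default_table()
        p = Path(self.recode_table)
        if p.suffix.lower() == ".json":
            return RecodeTable.from_json(p)
        return RecodeTable.from_csv(p, self.recode_policy)

    def intensity_model(self) -> IntensityModel:
        return IntensityModel(self.weight_developed, self.weight_agriculture)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        obj.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**obj)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


def _load_input(cfg: RunConfig, path: str) -> LandCoverRaster:
    table = cfg.recode()
    if table is None:
        return rio.read_raster(path, pixel_size=cfg.pixel_size)
    grid, ps, geotags = rio.read_grid(path, pixel_size=cfg.pixel_size)
    return apply_recode(grid, table, pixel_size=ps, geotags=geotags)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full product pipeline; returns the run summary dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out / "config.json")
    thr = cfg.thresholds()
    codes = cfg.codes()
    model = cfg.intensity_model()

    summary: dict = {"inputs": {}, "scales": {}, "change": {}}
    per_date = []
    for di, path in enumerate(cfg.inputs):
        tag = f"t{di + 1}"
        try:
            raster = _load_input(cfg, path)
        except Exception as exc:
            raise RuntimeError(f"[input {path}] {exc}") from exc
        comp, nodata_frac = map_composition(raster)
        summary["inputs"][tag] = {
            "path": str(path),
            "composition": {"a": comp.a, "n": comp.n, "d": comp.d},
            "nodata_fraction": nodata_frac,
        }
        log.info("input %s: composition a=%.3f n=%.3f d=%.3f", tag, comp.a, comp.n, comp.d)
        try:
            products = multiscale(raster, cfg.windows, thr, codes)
        except Exception as exc:
            raise RuntimeError(f"[classify {path}] {exc}") from exc
        per_date.append((tag, raster, products))

        for prod in products:
            w = prod.window.side
            stem = out / f"{tag}_w{w}"
            rio.write_array(prod.lm19.data, f"{stem}_lm19.tif", raster.geotags, nodata=0)
            rio.write_array(prod.lm103.data, f"{stem}_lm103.tif", raster.geotags, nodata=0)
            heatmap_to_csv(prod.heatmap, f"{stem}_heatmap.csv")
            inten = intensity_raster(prod.lm103, model)
            inten8 = np.where(np.isnan(inten), 255, np.rint(inten)).astype(np.uint8)
            rio.write_array(inten8, f"{stem}_intensity.tif", raster.geotags, nodata=255)
            if cfg.plot:
                import matplotlib
                matplotlib.use("Agg")
                ax = plot_heatmap(prod.heatmap)
                ax.figure.savefig(f"{stem}_heatmap.png", dpi=150)
                import matplotlib.pyplot as plt
                plt.close(ax.figure)
            scale_info = summary["scales"].setdefault(
                str(w), {"area_ha": prod.area_ha, "dates": {}}
            )
            info = {"heatmap_csv": f"{stem.name}_heatmap.csv"}
            for scheme in cfg.schemes:
                part = build_partition(scheme)
                labels, _ = apply_partition(prod.lm103, part)
                gs = group_summary(prod.heatmap, part)
                info[f"groups_{scheme}"] = gs.as_dict()
            scale_info["dates"][tag] = info

    if len(per_date) == 2:
        (tag1, _, prods1), (tag2, _, prods2) = per_date
        for p1, p2 in zip(prods1, prods2):
            w = p1.window.side
            stem = out / f"delta_w{w}"
            dh = delta_heatmap(p1.heatmap, p2.heatmap)
            heatmap_to_csv(dh, f"{stem}_heatmap.csv")
            i1 = intensity_raster(p1.lm103, model)
            i2 = intensity_raster(p2.lm103, model)
            delta = intensity_change(i1, i2)
            d16 = np.where(np.isnan(delta), CHANGE_NODATA, np.rint(delta)).astype(np.int16)
            rio.write_array(d16, f"{stem}_intensity_change.tif",
                            per_date[0][1].geotags, nodata=CHANGE_NODATA)
            stats = change_stats(delta)
            with open(f"{stem}_change_stats.json", "w") as fh:
                json.dump(stats.as_dict(), fh, indent=2)
            summary["change"][str(w)] = {
                "percent_unchanged": stats.percent_unchanged,
                "percent_changed": stats.percent_changed,
                "max_increase_cell": dh.max_increase_cell().kind,
            }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("pipeline complete: %s", out)
    return summary
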