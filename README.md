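# landmosaic

Multi-scale **landscape mosaic** analysis of categorical land-cover
rasters: moving-window ternary classification, heatmap summaries,
thematic reporting schemes, anthropic-intensity mapping, and two-date
change products.

## The problem

Landscape ecologists routinely need to know not just *what* a location is
(forest, crop, pavement) but what *surrounds* it: a forest pixel embedded
in cropland faces different pressures than one deep inside contiguous
forest. The landscape mosaic model answers this with a tri-polar
classification. For every pixel, the proportions of three base types —
agriculture (*A*), natural (*N*), developed (*D*) — are measured inside a
square moving window and the triple (*a, n, d*), with *a + n + d* = 1, is
placed on a ternary chart:

- **19-class scheme** — thresholds 0.1 / 0.6 / 1.0 on each axis. An
  uppercase letter marks a proportion in [0.6, 1) (dominance), a
  lowercase letter one in [0.1, 0.6) (presence), a missing letter one
  below 0.1; single-class windows get the corner labels `AA`, `NN`, `DD`.
  So `Nd` is natural-dominated land with a developed admixture and `adn`
  is the fully intermixed class.
- **103-class scheme** — the chart cut into decile cells: 55 upward and
  45 downward triangles of side 0.1 (floor binning of the proportions)
  plus the 3 exclusive corners (pixel codes 170 = `NN`, 180 = `AA`,
  190 = `DD`). Same information, ten times the thematic resolution.
- **Heatmap** — the percent frequency distribution of a map's pixels over
  the 103 cells; it always sums to 100%, so maps of different dates,
  extents, or analysis scales compare directly, and cellwise differences
  (delta heatmaps, summing to 0) localize change inside composition space.
- **Reporting schemes** — regroupings of the 103 cells: dominant
  background (`Ax`/`Nx`/`Dx`/`mixed`, 17+17+17+52 cells), diversity
  (`uniform`/`intermix`/`triple`/`dual`), refined mixed
  (`adn2`/`dn2`/`an2`/`ad2`, 16+12+12+12), and **anthropic intensity**:
  the linear score 100·(w_d·d̄ + w_a·ā) at each cell centroid with
  defaults w_d = 1, w_a = 0.5, anchored at 0% for pure natural and 100%
  for pure developed.

Windows shrink at map edges and skip nodata pixels (code 0), so
proportions are always over observed land; all decisions (purity, decile
indices, thresholds) are made in exact integer/rational arithmetic on
window counts.

## A worked example

```python
from landmosaic import (LandscapeParams, build_partition, group_summary,
                        multiscale, simulate_landscape)

raster = simulate_landscape(LandscapeParams(300, 300, proportions=(0.2, 0.6, 0.2),
                                            autocorr_length=10.0, seed=7))
background = build_partition("background")
for prod in multiscale(raster, windows=[7, 27, 81]):
    gs = group_summary(prod.heatmap, background)
    print(prod.window.side, round(prod.area_ha, 2), gs.as_dict())
```

prints (see `examples/02_multiscale_mosaic.py`):

```
window   area(ha)    Ax     Nx     Dx   mixed   (% of valid pixels)
    7       4.41   17.7   57.8   18.2    6.3
   27      65.61    9.4   54.4   11.4   24.8
   81     590.49    0.0   53.8    0.0   46.2
```

Each row is the background-scheme share of valid pixels at one analysis
scale (window side × 30 m pixels → hectares). The drift of mass from the
dominance groups into `mixed` as the window grows is the model's
characteristic scale behaviour: coarser neighbourhoods average over patch
boundaries, so fewer windows remain dominated by a single type.

More narrative scripts live in `examples/`: composition classification,
two-date change analysis (delta heatmap, percent unchanged, intensity
change), and re-theming one map with all four reporting schemes.

## Command line

```bash
landmosaic simulate demo.tif --rows 300 --cols 300 --seed 7 --convert 0.15
landmosaic run --input demo.tif --input demo_t2.tif -o products \
           --recode-table none -w 7 -w 13
landmosaic recode nlcd.tif lc.tif --table nlcd-default   # NLCD legend -> base types
```

`run` writes, per date and window: 19-class and 103-class GeoTIFFs, the
full-precision heatmap CSV, and the intensity map; with two dates also
delta-heatmap CSVs, intensity-change rasters, and change statistics.
Georeferencing tags of the input GeoTIFFs pass through unchanged.

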