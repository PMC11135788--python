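"""Re-theme one 103-class map with different reporting schemes.

The same mosaic raster can be displayed as dominant background land
cover, degree of diversity, or anthropic intensity, just by regrouping
the 103 chart cells — no reclassification of the raster is needed.
"""

from landmosaic import (
    LandscapeParams,
    LMCell,
    apply_partition,
    build_partition,
    classify_raster,
    compute_heatmap,
    group_summary,
    intensity_value,
    simulate_landscape,
    window_proportions,
)

raster = simulate_landscape(
    LandscapeParams(200, 200, (0.25, 0.5, 0.25), autocorr_length=6.0, seed=5)
)
_, lm103 = classify_raster(window_proportions(raster, 13))
heatmap = compute_heatmap(lm103)

for scheme in ("background", "diversity", "refined_mixed", "intensity"):
    part = build_partition(scheme)
    labels, colors = apply_partition(lm103, part)
    gs = group_summary(heatmap, part)
    shares = ", ".join(f"{k}={v:.1f}%" for k, v in gs.as_dict().items())
    print(f"{scheme:>14}: {shares}")

# Intensity anchors of the default model (developed weight 1, agriculture 0.5):
for cell, what in [(LMCell.corner("N"), "pure natural"),
                   (LMCell.corner("D"), "pure developed"),
                   (LMCell.up(0, 1, 8), "third cell from the developed corner")]:
    print(f"anthropic intensity {intensity_value(cell):5.1f}%  <- {what}")
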