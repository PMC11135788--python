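"""Classify window compositions on the ternary chart.

A location whose surrounding window is 75% agriculture, 15% natural and
10% developed sits in the agriculture-dominated interface zone: label
``Adn`` in the 19-class scheme, decile cell (7,1,1) in the 103-class one.
"""

from landmosaic import TernaryComposition, classify19, classify103, cell_to_19

for a, n, d in [(0.75, 0.15, 0.10), (0.2, 0.5, 0.3), (0.0, 1.0, 0.0),
                (0.05, 0.85, 0.10)]:
    comp = TernaryComposition(a, n, d)
    label = classify19(comp)
    cell = classify103(comp)
    print(f"(a={a:.2f}, n={n:.2f}, d={d:.2f})  ->  19-class {label.name:<4}"
          f" (code {label.code:>2})   103-class {cell.kind:<6} "
          f"({cell.la},{cell.ln},{cell.ld})  -> back to {cell_to_19(cell).name}")

# The 19-class name encodes thresholds: uppercase = proportion in [0.6, 1),
# lowercase = [0.1, 0.6), doubled letters = a single-class window.
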