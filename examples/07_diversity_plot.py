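"""Render a diversity tree plot.

Each clonotype is a spot: position encodes its (V, J) combination on a
mosaic grid whose cell areas track frequency mass, spot area is
proportional to clonal frequency, and every spot gets a unique color.
Dominant clones show up as large spots.
"""

import math

from trirep import builtin_library, simulate_repertoire
from trirep.plot import PlotSpec, floored_spots, layout_diversity_plot, render

lib = builtin_library()
rep = simulate_repertoire(lib, 1500, abundance_shape=1.2, seed=21,
                          donor_id="II", lineage="CD14").to_repertoire()

spec = PlotSpec(width=800, height=600, color_seed=21)
spots = layout_diversity_plot(rep, spec)
path = render(spots, "diversity_II_CD14.svg", spec)

areas = [math.pi * s.nominal_radius**2 for s in spots]
print(f"{len(spots)} spots -> {path}")
print(f"largest spot covers {max(areas) / sum(areas) * 100:.1f}% of the spot budget "
      f"(= the top clone's share of the repertoire)")
print(f"spots adjusted for visibility/fit: {len(floored_spots(spots))}")
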