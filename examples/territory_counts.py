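"""Voronoi perfusion territories and the per-region count table.

Every PA's supplied territory is approximated by its Voronoi cell; a PA
counts toward a sensory region only when the majority of its cell lies
inside the region (so boundary-straddling PAs are attributed where they
actually perfuse).
"""

import numpy as np

from pialnet import GeneratorParams, generate_animal_network, generate_geometry
from pialnet.territories import (assign_pa_regions, build_count_table,
                                 voronoi_tiling)

params = GeneratorParams(seed=12)
rng = np.random.default_rng(12)
regions = generate_geometry(params, rng)
sample = generate_animal_network(regions, params, "sham", rng)

seeds = {n.id: (n.x_mm, n.y_mm) for n in sample.network.pa_nodes()}
tiling = voronoi_tiling(seeds, regions.slab)
print(f"{len(seeds)} PA territories tile the {regions.slab.area:.1f} mm^2 slab "
      f"(cells sum to {sum(tiling.cell_areas_mm2.values()):.6f} mm^2)")

assigned = assign_pa_regions(tiling, regions)
in_region = sum(1 for r in assigned.values() if r is not None)
print(f"{in_region} PAs fall inside a sensory region by the majority rule")

table = build_count_table([sample], "pa")
print("\nper-region PA counts and densities:")
for _, row in table.df.iterrows():
    print(f"  {row.region:<9} C={row['count']:>3}  A={row.area_mm2:.2f} mm^2  "
          f"density={row['count'] / row.area_mm2:5.1f} /mm^2")
# densities hover around the generator intensity of 17.4/mm^2 scaled by
# this animal's random intercept.
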