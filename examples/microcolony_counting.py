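"""Count microcolonies founded by individual cells inside one droplet.

In a droplet, each founder cell develops its own microcolony; the colonies
stay spatially distinct until the culture approaches saturation.  The
generator records a "checkpoint" frame where every colony is large enough
to segment but none have merged — there the count equals the number of
founder cells.
"""

import numpy as np

from moca import imaging
from moca import scene as sc

syn = sc.build_scene(
    sc.DropletLayout(n_rows=1, n_cols=1), counts=[3],
    growth=sc.GrowthParams(lag_sd_h=0.5), seed=9,
)
stack, truth = sc.render_stack(syn)
row = truth.iloc[0]
roi = imaging.locate_droplets(stack, syn.layout, mode="grid")[0]

checkpoint = int(row.checkpoint_frame)
count, centroids = imaging.count_microcolonies(stack[0, checkpoint], roi)
print(f"seeded cells: {row.cell_count}")
print(f"checkpoint frame {checkpoint} (t = {syn.times_h[checkpoint]:.1f} h): "
      f"{count} microcolonies at {[tuple(round(c) for c in p) for p in centroids]}")
# The count equals the seeded cell number: one microcolony per founder.

merge_frame = int(np.searchsorted(syn.times_h, row.merge_time_h))
late, _ = imaging.count_microcolonies(stack[0, merge_frame], roi)
print(f"merge frame {merge_frame} (t = {row.merge_time_h:.1f} h): {late} components")
# Once colonies touch they fuse into fewer connected components, so counts
# are only meaningful before the ground-truth merge time.
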