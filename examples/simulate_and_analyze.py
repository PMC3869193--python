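"""Simulate a small droplet-array time-lapse and read out growth statistics.

Builds a 2 x 3 array loaded at 10 cells/ul (1-ul droplets), renders the
bright-field stack at 30-min cadence for 24 h, extracts each droplet's
transmission curve, and prints the threshold growth time — the time at
which the normalized transmission first intersects 0.99.
"""

import numpy as np

from moca import growth, imaging
from moca import scene as sc

layout = sc.DropletLayout(n_rows=2, n_cols=3)
syn = sc.plan_experiment(
    layout, concentrations=[10.0], droplets_per_concentration=6,
    volume_ul=1.0, seed=5, times_h=sc.default_times(24.0, 0.5),
)
stack, truth = sc.render_stack(syn)
print(f"rendered stack: {stack.shape} (droplets, frames, H, W)")

rois = imaging.locate_droplets(stack, layout, mode="grid")
series = imaging.extract_transmission(stack, rois, syn.times_h)
results = growth.analyze_experiment(
    series, {d.droplet_id: d.group for d in syn.droplets}
)

print("droplet  cells  grew  threshold_h  true_threshold_h")
for r, (_, row) in zip(results, truth.iterrows()):
    t = f"{r.threshold_time_h:11.2f}" if r.grew else "          -"
    tt = f"{row.true_threshold_time_h:8.2f}" if not np.isnan(row.true_threshold_time_h) else "       -"
    print(f"{r.droplet_id:>7}  {row.cell_count:>5}  {str(r.grew):>4}  {t}  {tt}")
# The measured crossing matches the generator's latent-signal ground truth
# to well within one 0.5-h frame; droplets with more founder cells cross
# earlier (about ln(10)/mu hours earlier per tenfold inoculum).

(summary,) = growth.summarize_groups(results)
print(
    f"\ngroup {summary.group:g} cells/droplet: {summary.n_grew}/{summary.n_droplets} grew, "
    f"median threshold {summary.median_h:.2f} h (IQR {summary.q1_h:.2f}-{summary.q3_h:.2f})"
)
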