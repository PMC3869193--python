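"""Detect the post-peak transmission rebound of sporulating cultures.

Some spore-formers brighten again after their population peaks: the cell
number stays constant but cells shrink as they sporulate, so the droplet
recovers part of its attenuation.  The scene generator reproduces this with
``sporulation=True``; the analysis flags it and reports the onset (the
minimum of the smoothed curve), which coincides with the population plateau.
"""

from moca import growth, imaging
from moca import scene as sc

layout = sc.DropletLayout(n_rows=1, n_cols=3)
params = sc.GrowthParams(sporulation=True, rebound_fraction=0.3, lag_sd_h=0.5)
syn = sc.build_scene(layout, counts=[1, 1, 2], growth=params, seed=101)
stack, truth = sc.render_stack(syn)
rois = imaging.locate_droplets(stack, layout, mode="grid")
series = imaging.extract_transmission(stack, rois, syn.times_h)

print("droplet  rebound  onset_h  true_plateau_h  curve_min  curve_final")
for s, (_, row) in zip(series, truth.iterrows()):
    norm = growth.normalize_curve(s)
    flag, onset = growth.detect_rebound(norm, s.times_h)
    print(
        f"{s.droplet_id:>7}  {str(flag):>7}  {onset:7.2f}  {row.plateau_time_h:14.2f}"
        f"  {norm.min():9.3f}  {norm[-1]:11.3f}"
    )
# Every sporulating droplet is flagged, with the detected onset within one
# hour of the ground-truth plateau; the final value sits clearly above the
# minimum because 30% of the peak attenuation is recovered.
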