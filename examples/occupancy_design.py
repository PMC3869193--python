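"""Poisson occupancy design for droplet loading.

Shows the occupancy distribution at the classic one-cell-per-droplet
loading, the multicell risk at the marine-sample dilution (0.25 cells per
droplet), and the inverse problem: which dilution achieves a wanted
single-cell fraction.
"""

from moca import occupancy as occ

# 1 cell/ul loaded into 1-ul droplets -> lambda = 1 cell per droplet
lam = occ.lambda_from_loading(concentration=1.0, volume=1.0)
ks, ps = occ.occupancy_table(lam, max_k=4)
print(f"lambda = {lam:g} cells/droplet")
for k, p in zip(ks, ps):
    print(f"  P(K={k}) = {100 * p:5.2f}%")
# ~37% of droplets are empty and ~37/18/6/1.5% hold 1..4 cells: at this
# loading roughly every third droplet starts from a single founder cell.

# marine dilution: 0.25 cells per droplet
print(f"\nlambda = 0.25 cells/droplet")
print(f"  single-cell fraction P(K=1)  = {100 * occ.single_cell_probability(0.25):.2f}%")
print(f"  multicell risk     P(K>=2)   = {100 * occ.multicell_probability(0.25):.2f}%")
# ~19.5% of droplets are pure single-cell cultures while only ~2.7% risk
# containing more than one founder.

# inverse design: what lambda gives exactly a 20% single-cell fraction?
lam20 = occ.solve_lambda_for_single_fraction(0.20, branch="low")
print(f"\nP(K=1) = 20% (dilute branch) at lambda = {lam20:.4f} cells/droplet")
print(f"  multicell risk there: {100 * occ.multicell_probability(lam20):.2f}%")
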