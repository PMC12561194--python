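"""Build a two-basin ensemble and recover its free-energy landscape.

Generates 2000 frames with 90%/10% basin occupancy, computes RMSD/Rg
reaction coordinates, bins them into a free-energy surface and reports
the gap between the global and metastable minima.  For a two-state
system the gap should equal kB·T·ln(p1/p2) = 1.31 kcal/mol at 300 K.
"""

import numpy as np

import pocketshaper as ps
from pocketshaper.core import resolve_selection
from pocketshaper.landscape import KB_KCAL, compute_fel, find_minima, representative_frame, rg_series, rmsd_series

spec = ps.synthetic.default_two_basin_spec(
    n_frames=2000, occupancies=(0.9, 0.1), planted_prs=None, seed=29
)
ensemble, truth = ps.synthetic.generate_two_basin_ensemble(spec)

backbone = resolve_selection(ensemble.topology, "name CA")
x = rmsd_series(ensemble, backbone, ensemble.frames[0])
y = rg_series(ensemble, backbone)
surface = compute_fel(x, y, bins=(8, 8), temperature_K=300.0)
basins = find_minima(surface, min_separation_bins=3, x=x, y=y)

print(f"frames: {ensemble.n_frames}, occupied bins: {int(surface.occupied.sum())}")
for b in basins:
    rep = representative_frame(b, surface, x, y)
    print(
        f"{b.kind:6s} basin at bin {b.bin_index}: ΔG = {b.delta_g:.3f} kcal/mol, "
        f"{len(b.member_frames)} member frames, representative frame {rep}"
    )
gap = basins[1].delta_g - basins[0].delta_g
print(f"recovered ΔΔG = {gap:.3f} kcal/mol "
      f"(two-state expectation {KB_KCAL * 300 * np.log(9):.3f})")
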