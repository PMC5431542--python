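"""Hydrogen- and halogen-bond detection with geometric criteria.

Hydrogen bond: donor-acceptor < 3.0 Å with donor-H-acceptor > 120°.
Halogen bond: X···acceptor ≤ 3.5 Å with a near-linear C-X···acceptor
angle (≥ 140°), the σ-hole geometry.  In the synthetic scene an occupied
hydration-site water donates a hydrogen bond to the E762 carboxylate
(2.8 Å) and accepts a halogen bond from the ligand fluorine (3.0 Å).
"""

import numpy as np

from kinpocket import (
    SyntheticSpec, find_halogen_bonds, find_hbonds, generate,
    resolve_selection, xbond_distance_series,
)

spec = SyntheticSpec(n_frames=500, seed=3)
topology, frames, truth = generate(spec)
frame_idx = int(np.flatnonzero(truth.occupied)[0])
coords = frames[frame_idx]

waters = resolve_selection(topology, "water and name O")
carboxylate = resolve_selection(topology, "resid 762 and name OE1 OE2")
fluorine = resolve_selection(topology, "resname LIG and name F1")

for rec in find_hbonds(coords, topology, waters, carboxylate,
                       frame_index=frame_idx, warn_missing_h=False):
    print(f"H-bond:  donor atom {rec.donor_index} -> acceptor {rec.acceptor_index}  "
          f"d = {rec.distance:.2f} A, angle = {rec.angle:.0f} deg")

for rec in find_halogen_bonds(coords, topology, fluorine, waters,
                              frame_index=frame_idx):
    print(f"X-bond:  halogen atom {rec.donor_index} -> acceptor {rec.acceptor_index}  "
          f"d = {rec.distance:.2f} A, C-X...A = {rec.angle:.0f} deg")

# Raw halogen-ligand distances are tracked independently of the cutoff,
# so bond lengths can be followed even when a pair drifts out of range.
wo = int(waters.indices[0])
series = xbond_distance_series(frames, int(fluorine.indices[0]), wo)
print(f"\nF...O(water {topology.res_ids[wo]}) distance over the trajectory: "
      f"min {series.values.min():.1f} A, max {series.values.max():.1f} A")
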