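"""Binding-pocket size: distance between the αC-helix and hinge centres of mass.

An inward (compacted) αC-helix shrinks the ATP/inhibitor pocket; tracking
|COM(helix) − COM(hinge)| per frame quantifies that compaction.  Here the
synthetic scene plants a breathing pocket (20.5 ± 0.8 Å), and the metric
recovers the planted distances to numerical precision.
"""

import numpy as np

from kinpocket import (
    SyntheticSpec, distribution, generate, pocket_size_series,
    resolve_selection,
)

spec = SyntheticSpec(n_frames=2000, seed=42)
topology, frames, truth = generate(spec)

helix = resolve_selection(topology, "resid 759:761", label="alphaC helix")
hinge = resolve_selection(topology, "resid 790:792", label="hinge")
series = pocket_size_series(frames, helix, hinge, topology.masses)

print(f"frames analysed:      {series.n_frames} ({series.times[-1]/1000:.0f} ns)")
print(f"mean pocket size:     {series.values.mean():.3f} A")
print(f"pocket size range:    {series.values.min():.3f} - {series.values.max():.3f} A")
print(f"max |error| vs planted: {np.abs(series.values - truth.pocket_distances).max():.2e} A")

dist = distribution(series, bin_width=0.1)
peak = np.argmax(dist.probabilities)
print(f"modal bin:            [{dist.bin_edges[peak]:.1f}, {dist.bin_edges[peak+1]:.1f}) A "
      f"(p = {dist.probabilities[peak]:.3f})")
print("\nA smaller mean distance means a more compact pocket; comparing the")
print("distributions between systems shows compaction shifts of several A.")
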