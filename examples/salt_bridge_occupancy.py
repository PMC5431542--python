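"""Salt-bridge occupancy from a minimum side-chain heavy-atom distance series.

A salt bridge is scored as formed in a frame when the closest approach of
the two charged side chains is below 3.5 Å.  The synthetic R858–E758 pair
switches between a bound (2.9 Å) and a separated (12 Å) state with a
planted 40% bound fraction; the occupancy statistic recovers exactly the
fraction the generator realised.
"""

from kinpocket import (
    SyntheticSpec, distribution, generate, min_group_distance_series,
    resolve_selection, saltbridge_occupancy,
)

spec = SyntheticSpec(n_frames=10_000, seed=7)
topology, frames, truth = generate(spec)

arg = resolve_selection(topology, "resid 858 and sidechain and heavy")
glu = resolve_selection(topology, "resid 758 and sidechain and heavy")
series = min_group_distance_series(frames, arg, glu, label="R858-E758")

occ = saltbridge_occupancy(series)
print(f"frames analysed:        {series.n_frames}")
print(f"planted bound fraction: {truth.p_bound:.3f}")
print(f"realized bound fraction:{truth.realized_bound_fraction:.4f}")
print(f"measured occupancy:     {occ:.4f}   (distance < 3.5 A)")

dist = distribution(series, bin_width=0.1)
print(f"mass below 3.5 A from the distribution: {dist.fraction_below(3.5):.4f}")
print("\nThe occupancy equals the realized state fraction exactly; it differs")
print("from the planted 0.400 only by finite-trajectory sampling noise.")
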