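"""Bridging-water identification and identity-agnostic residence times.

A hydration site is defined by dual proximity: a water molecule (probed
by its oxygen) bridges the inhibitor and the protein when its oxygen is
simultaneously within the proximity cutoff (default 3.5 Å) of at least
one ligand-anchor atom and one protein-anchor atom.  Site occupancy is a
property of the site, not of any particular water: when one water leaves
and another exchanges with it, the occupancy clock keeps running.  The
residence time is the summed time the site holds any water; the longest
contiguous interval is reported alongside because the two readings of
"residence time" differ whenever exchanges interleave with dry frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .interactions import (
    InteractionCriteria,
    InteractionRecord,
    find_halogen_bonds,
    find_hbonds,
)
from .io import AtomSelection, FrameSeries, Topology

__all__ = [
    "HydrationSiteSpec",
    "OccupancySeries",
    "ResidenceResult",
    "WaterBridge",
    "find_bridging_waters",
    "site_occupancy",
    "residence_time",
    "water_mediated_records",
]


@dataclass
class HydrationSiteSpec:
    """Defines one hydration site by its two anchors and a water probe.

    ``water_probe`` must select exactly one oxygen per water residue; the
    water's residue number serves as its identity.
    """

    ligand_anchor: AtomSelection
    protein_anchor: AtomSelection
    water_probe: AtomSelection
    proximity_cut: float = 3.5
    label: str = "site"

    def __post_init__(self):
        if self.ligand_anchor.is_empty or self.protein_anchor.is_empty:
            raise ValueError(f"site '{self.label}': anchors must be non-empty")
        if not self.proximity_cut > 0:
            raise ValueError("proximity_cut must be positive")
        probe = set(self.water_probe.indices.tolist())
        for anchor in (self.ligand_anchor, self.protein_anchor):
            if probe & set(anchor.indices.tolist()):
                raise ValueError(
                    f"site '{self.label}': anchor overlaps the water probe"
                )


@dataclass
class OccupancySeries:
    """Per-frame site occupancy and the identities of occupying waters."""

    occupied: np.ndarray  # bool per frame
    water_ids: list[frozenset[int]]
    dt: float
    t0: float = 0.0
    label: str = "site"

    def __post_init__(self):
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if len(self.occupied) != len(self.water_ids):
            raise ValueError("occupied and water_ids lengths differ")
        for i, ids in enumerate(self.water_ids):
            if bool(self.occupied[i]) != bool(ids):
                raise ValueError(
                    f"frame {i}: occupied flag inconsistent with id set"
                )

    @property
    def n_frames(self) -> int:
        return len(self.occupied)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    def occupancy_fraction(self) -> float:
        return float(self.occupied.mean()) if self.n_frames else 0.0


@dataclass
class ResidenceResult:
    """Identity-agnostic residence-time summary for one hydration site.

    ``total_time`` sums every occupied frame; ``intervals`` are maximal
    occupied runs (ps, half-open: a frame at time t covers [t, t+dt));
    ``n_exchange_events`` counts frames where the occupying water set
    changes while the site stays occupied.
    """

    total_time: float
    longest_interval: float
    intervals: list[tuple[float, float]]
    n_exchange_events: int

    def __post_init__(self):
        if self.longest_interval > self.total_time + 1e-9:
            raise ValueError("longest interval cannot exceed total time")


def find_bridging_waters(
    coords: np.ndarray, topology: Topology, site: HydrationSiteSpec
) -> set[int]:
    """Residue ids of waters bridging the two anchors in one frame.

    A water qualifies when its probe oxygen lies within
    ``site.proximity_cut`` of at least one ligand-anchor atom AND at
    least one protein-anchor atom.
    """
    probe = site.water_probe.indices
    if len(probe) == 0:
        return set()
    xyz = np.asarray(coords, dtype=np.float64)
    d_lig = cdist(xyz[probe], xyz[site.ligand_anchor.indices])
    d_pro = cdist(xyz[probe], xyz[site.protein_anchor.indices])
    near = (d_lig.min(axis=1) <= site.proximity_cut) & (
        d_pro.min(axis=1) <= site.proximity_cut
    )
    return {int(topology.res_ids[probe[i]]) for i in np.flatnonzero(near)}


def site_occupancy(
    traj: FrameSeries, topology: Topology, site: HydrationSiteSpec
) -> OccupancySeries:
    """Per-frame bridging-water sets; occupied iff any water qualifies.

    Identity-agnostic by construction: the occupied flag depends only on
    whether the set is non-empty, never on which water supplies it.
    """
    ids = [
        frozenset(find_bridging_waters(traj[i], topology, site))
        for i in range(traj.n_frames)
    ]
    occupied = np.array([bool(s) for s in ids])
    return OccupancySeries(
        occupied=occupied, water_ids=ids, dt=traj.dt, t0=traj.t0,
        label=site.label,
    )


def residence_time(
    occ: OccupancySeries, gap_tolerance_frames: int | float = 0
) -> ResidenceResult:
    """Summed, identity-agnostic residence time of a hydration site.

    ``total_time`` = (number of occupied frames) · dt, regardless of gap
    bridging.  Intervals are maximal occupied runs after bridging
    unoccupied gaps of at most ``gap_tolerance_frames`` frames (bridged
    gap frames do not add to the total).  ``math.inf`` is accepted and
    collapses everything into a single first-to-last-occupied interval.
    """
    if occ.n_frames == 0:
        raise ValueError("occupancy series is empty")
    if gap_tolerance_frames < 0:
        raise ValueError("gap tolerance cannot be negative")
    occupied = occ.occupied
    dt, t0 = occ.dt, occ.t0
    total_time = float(occupied.sum()) * dt

    occ_frames = np.flatnonzero(occupied)
    intervals: list[tuple[float, float]] = []
    if len(occ_frames):
        run_start = prev = occ_frames[0]
        for f in occ_frames[1:]:
            gap = f - prev - 1
            if gap > gap_tolerance_frames:
                intervals.append((float(t0 + run_start * dt),
                                  float(t0 + (prev + 1) * dt)))
                run_start = f
            prev = f
        intervals.append((t0 + run_start * dt, t0 + (prev + 1) * dt))

    longest = 0.0
    for start, end in intervals:
        # Bridged gaps inside a run do not count toward its length.
        i0 = int(round((start - t0) / dt))
        i1 = int(round((end - t0) / dt))
        length = float(occupied[i0:i1].sum()) * dt
        longest = max(longest, length)

    exchanges = 0
    for i in range(1, occ.n_frames):
        if occupied[i - 1] and occupied[i] and occ.water_ids[i] != occ.water_ids[i - 1]:
            exchanges += 1
    return ResidenceResult(
        total_time=total_time,
        longest_interval=longest,
        intervals=intervals,
        n_exchange_events=exchanges,
    )


@dataclass
class WaterBridge:
    """One water simultaneously engaging both sides of a hydration site.

    A bridge requires at least one qualifying hydrogen- or halogen-bond
    record on the protein side and on the ligand side; the component
    records are kept for reporting.
    """

    frame_index: int
    water_id: int
    protein_records: list[InteractionRecord]
    ligand_records: list[InteractionRecord]


def _water_atom_indices(topology: Topology, site: HydrationSiteSpec,
                        water_id: int) -> np.ndarray:
    probe_chains = set(topology.chain_ids[site.water_probe.indices].tolist())
    mask = (topology.res_ids == water_id) & np.isin(
        topology.chain_ids, sorted(probe_chains)
    ) & topology.is_water
    return np.flatnonzero(mask)


def water_mediated_records(
    coords: np.ndarray,
    topology: Topology,
    site: HydrationSiteSpec,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame_index: int = 0,
) -> list[WaterBridge]:
    """Water-mediated interaction bridges in one frame.

    For each bridging water: hydrogen bonds water↔protein-anchor and
    water↔ligand-anchor (both donation directions) plus halogen bonds
    from ligand halogens to the water oxygen.  Water O–H bonding is
    resolved by residue membership, not geometry, since water hydrogens
    are rotationally labile.
    """
    bridges = []
    for water_id in sorted(find_bridging_waters(coords, topology, site)):
        watoms = _water_atom_indices(topology, site, water_id)
        wsel = AtomSelection(label=f"water {water_id}", indices=watoms)
        w_o = watoms[topology.elements[watoms] == "O"]
        w_h = [int(h) for h in watoms[topology.elements[watoms] == "H"]]
        h_map = {int(o): w_h for o in w_o}

        def hbonds_between(donor_sel, acceptor_sel, extra_map=None):
            # Anchors that cannot donate (e.g. carboxylate oxygens) are
            # expected; skip them quietly.
            return find_hbonds(
                coords, topology, donor_sel, acceptor_sel, criteria,
                frame_index=frame_index, donor_h_map=extra_map,
                warn_missing_h=False,
            )

        protein_records = (
            hbonds_between(wsel, site.protein_anchor, h_map)
            + hbonds_between(site.protein_anchor, wsel)
        )
        ligand_records = (
            hbonds_between(wsel, site.ligand_anchor, h_map)
            + hbonds_between(site.ligand_anchor, wsel)
            + find_halogen_bonds(
                coords, topology, site.ligand_anchor, wsel, criteria,
                frame_index=frame_index,
            )
        )
        if protein_records and ligand_records:
            bridges.append(WaterBridge(
                frame_index=frame_index, water_id=water_id,
                protein_records=protein_records,
                ligand_records=ligand_records,
            ))
    return bridges
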