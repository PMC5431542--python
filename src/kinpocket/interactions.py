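"""Hydrogen-bond, halogen-bond, contact and salt-bridge detection.

Geometric criteria (all configurable through :class:`InteractionCriteria`):

* hydrogen bond — donor–acceptor distance strictly below 3.0 Å and a
  donor–hydrogen–acceptor angle strictly above 120°;
* heavy-atom contact — cross-pair distance within (≤) 6.5 Å;
* salt bridge — minimum side-chain heavy-atom distance strictly below
  3.5 Å;
* halogen bond — X···acceptor distance ≤ 3.5 Å with a C–X···acceptor
  angle ≥ 140° (near-linear σ-hole geometry).  Raw X···A distances are
  always carried in the records so bond lengths can be tracked even for
  pairs that drift above the cutoff.

Donor chemistry: donors are N/O heavy atoms carrying at least one bonded
hydrogen; acceptors are N/O/F.  Covalent bonds are inferred geometrically
(H within 1.2 Å of the donor, halogen's nearest carbon) from a designated
bonding frame — frame 0 by convention — since PDB inputs rarely carry
CONECT records.  On hydrogen-free topologies hydrogen-bond detection
degrades to a distance-only mode (records carry ``angle=None``) rather
than silently returning nothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import ScalarSeries
from .io import AtomSelection, FrameSeries, Topology

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "infer_donor_hydrogens",
    "infer_halogen_carbons",
    "find_hbonds",
    "find_halogen_bonds",
    "contact_count",
    "mean_contacts",
    "saltbridge_occupancy",
    "xbond_distance_series",
]

_HALOGENS = frozenset({"F", "Cl", "Br", "I"})
_ACCEPTOR_ELEMENTS = frozenset({"N", "O", "F"})
_DONOR_ELEMENTS = frozenset({"N", "O"})
_DH_BOND_CUT = 1.2  # Å, covalent donor-H inference
_CX_BOND_CUT = 2.0  # Å, covalent carbon-halogen inference


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs governing all detectors (Å and degrees)."""

    hbond_da_cut: float = 3.0
    hbond_angle_cut: float = 120.0
    contact_cut: float = 6.5
    saltbridge_cut: float = 3.5
    xbond_dist_cut: float = 3.5
    xbond_angle_cut: float = 140.0

    def __post_init__(self):
        for name in ("hbond_da_cut", "contact_cut", "saltbridge_cut",
                     "xbond_dist_cut"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_angle_cut", "xbond_angle_cut"):
            val = getattr(self, name)
            if not 0 < val <= 180:
                raise ValueError(f"{name} must lie in (0, 180]")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected interaction in one frame.

    ``donor_index`` holds the donor heavy atom for hydrogen bonds and the
    halogen for halogen bonds; ``hydrogen_index`` is None for halogen
    bonds and in distance-only hydrogen-bond mode, where ``angle`` is
    None as well.
    """

    frame_index: int
    kind: str  # "hbond" | "xbond" | "contact-pair"
    donor_index: int
    acceptor_index: int
    distance: float
    hydrogen_index: int | None = None
    angle: float | None = None


def _angle_deg(apex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Angle a-apex-b in degrees."""
    v1 = a - apex
    v2 = b - apex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def infer_donor_hydrogens(
    topology: Topology,
    bond_coords: np.ndarray,
    donor_indices: np.ndarray,
) -> dict[int, list[int]]:
    """Map each donor heavy atom to hydrogens within 1.2 Å in the bonding frame."""
    h_idx = np.flatnonzero(topology.elements == "H")
    mapping: dict[int, list[int]] = {int(d): [] for d in donor_indices}
    if len(h_idx) == 0 or len(donor_indices) == 0:
        return mapping
    xyz = np.asarray(bond_coords, dtype=np.float64)
    dists = cdist(xyz[donor_indices], xyz[h_idx])
    for di, d in enumerate(donor_indices):
        for hj in np.flatnonzero(dists[di] <= _DH_BOND_CUT):
            mapping[int(d)].append(int(h_idx[hj]))
    return mapping


def infer_halogen_carbons(
    topology: Topology,
    bond_coords: np.ndarray,
    halogen_indices: np.ndarray,
) -> dict[int, int]:
    """Map each halogen to its covalently bonded carbon (nearest C ≤ 2.0 Å)."""
    c_idx = np.flatnonzero(topology.elements == "C")
    mapping: dict[int, int] = {}
    if len(c_idx) == 0:
        return mapping
    xyz = np.asarray(bond_coords, dtype=np.float64)
    dists = cdist(xyz[halogen_indices], xyz[c_idx])
    for xi, x in enumerate(halogen_indices):
        j = int(np.argmin(dists[xi]))
        if dists[xi, j] <= _CX_BOND_CUT:
            mapping[int(x)] = int(c_idx[j])
    return mapping


def find_hbonds(
    coords: np.ndarray,
    topology: Topology,
    donor_sel: AtomSelection,
    acceptor_sel: AtomSelection,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame_index: int = 0,
    bond_coords: np.ndarray | None = None,
    donor_h_map: dict[int, list[int]] | None = None,
    warn_missing_h: bool = True,
) -> list[InteractionRecord]:
    """Detect hydrogen bonds between donor and acceptor groups in one frame.

    Donors are the N/O atoms of ``donor_sel``; acceptors the N/O/F atoms
    of ``acceptor_sel``.  Each (donor, H, acceptor) triple is evaluated
    independently; records are deduplicated per (donor, acceptor) keeping
    the widest angle.  A donor with no resolvable hydrogen is skipped with
    a logged warning.  If the topology has no hydrogens at all, detection
    falls back to distance-only records (``angle=None``).

    ``bond_coords`` designates the frame used for covalent-H inference
    (default: this frame); a prebuilt ``donor_h_map`` overrides geometric
    inference, e.g. to bond waters by residue membership.
    """
    xyz = np.asarray(coords, dtype=np.float64)
    donors = np.array(
        [i for i in donor_sel.indices if topology.elements[i] in _DONOR_ELEMENTS],
        dtype=int,
    )
    acceptors = np.array(
        [i for i in acceptor_sel.indices
         if topology.elements[i] in _ACCEPTOR_ELEMENTS],
        dtype=int,
    )
    if len(donors) == 0 or len(acceptors) == 0:
        return []

    distance_only = not topology.has_hydrogens()
    if not distance_only and donor_h_map is None:
        donor_h_map = infer_donor_hydrogens(
            topology, bond_coords if bond_coords is not None else xyz, donors
        )

    da = cdist(xyz[donors], xyz[acceptors])
    best: dict[tuple[int, int], InteractionRecord] = {}
    for di, d in enumerate(donors):
        hydrogens = None
        if not distance_only:
            hydrogens = donor_h_map.get(int(d), []) if donor_h_map else []
            if not hydrogens:
                if warn_missing_h:
                    logger.warning(
                        "hbond donor atom %d (%s/%s/%s) has no bonded "
                        "hydrogen; skipped",
                        d, topology.chain_ids[d], topology.res_ids[d],
                        topology.atom_names[d],
                    )
                continue
        for ai, a in enumerate(acceptors):
            if a == d:
                continue
            dist = da[di, ai]
            if not dist < criteria.hbond_da_cut:
                continue
            if distance_only:
                rec = InteractionRecord(
                    frame_index=frame_index, kind="hbond",
                    donor_index=int(d), acceptor_index=int(a),
                    distance=float(dist),
                )
                best.setdefault((int(d), int(a)), rec)
                continue
            for h in hydrogens:
                if h == a:
                    continue
                angle = _angle_deg(xyz[h], xyz[d], xyz[a])
                if angle > criteria.hbond_angle_cut:
                    key = (int(d), int(a))
                    prev = best.get(key)
                    if prev is None or (prev.angle or 0.0) < angle:
                        best[key] = InteractionRecord(
                            frame_index=frame_index, kind="hbond",
                            donor_index=int(d), hydrogen_index=int(h),
                            acceptor_index=int(a),
                            distance=float(dist), angle=float(angle),
                        )
    return sorted(best.values(),
                  key=lambda r: (r.donor_index, r.acceptor_index))


def find_halogen_bonds(
    coords: np.ndarray,
    topology: Topology,
    halogen_sel: AtomSelection,
    acceptor_sel: AtomSelection,
    criteria: InteractionCriteria = InteractionCriteria(),
    frame_index: int = 0,
    bond_coords: np.ndarray | None = None,
    carbon_map: dict[int, int] | None = None,
) -> list[InteractionRecord]:
    """Detect halogen (σ-hole) bonds X···A in one frame.

    A record is emitted per (halogen, acceptor) pair with X···A distance
    ≤ ``xbond_dist_cut`` and C–X···A angle ≥ ``xbond_angle_cut``.  A
    halogen without a bonded carbon is skipped with a warning.
    """
    xyz = np.asarray(coords, dtype=np.float64)
    halogens = np.array(
        [i for i in halogen_sel.indices if topology.elements[i] in _HALOGENS],
        dtype=int,
    )
    acceptors = np.array(
        [i for i in acceptor_sel.indices
         if topology.elements[i] in _ACCEPTOR_ELEMENTS],
        dtype=int,
    )
    if len(halogens) == 0 or len(acceptors) == 0:
        return []
    if carbon_map is None:
        carbon_map = infer_halogen_carbons(
            topology, bond_coords if bond_coords is not None else xyz, halogens
        )
    records = []
    xa = cdist(xyz[halogens], xyz[acceptors])
    for xi, x in enumerate(halogens):
        carbon = carbon_map.get(int(x))
        if carbon is None:
            logger.warning(
                "halogen atom %d (%s) has no bonded carbon; skipped",
                x, topology.atom_names[x],
            )
            continue
        for ai, a in enumerate(acceptors):
            if a == x or a == carbon:
                continue
            dist = xa[xi, ai]
            if dist > criteria.xbond_dist_cut:
                continue
            angle = _angle_deg(xyz[x], xyz[carbon], xyz[a])
            if angle >= criteria.xbond_angle_cut:
                records.append(InteractionRecord(
                    frame_index=frame_index, kind="xbond",
                    donor_index=int(x), acceptor_index=int(a),
                    distance=float(dist), angle=float(angle),
                ))
    return records


def contact_count(
    coords: np.ndarray,
    topology: Topology,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> int:
    """Number of heavy-atom cross pairs within (≤) the contact cutoff.

    Hydrogens are filtered from both selections before counting.
    """
    a = sel_a.indices[topology.elements[sel_a.indices] != "H"]
    b = sel_b.indices[topology.elements[sel_b.indices] != "H"]
    if len(a) == 0 or len(b) == 0:
        return 0
    xyz = np.asarray(coords, dtype=np.float64)
    d = cdist(xyz[a], xyz[b])
    same = a[:, None] == b[None, :]
    return int(np.sum((d <= criteria.contact_cut) & ~same))


def mean_contacts(
    traj: FrameSeries,
    topology: Topology,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> float:
    """Arithmetic mean of :func:`contact_count` over all frames."""
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    counts = [
        contact_count(traj[i], topology, sel_a, sel_b, criteria)
        for i in range(traj.n_frames)
    ]
    return float(np.mean(counts))


def contact_count_series(
    traj: FrameSeries,
    topology: Topology,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    criteria: InteractionCriteria = InteractionCriteria(),
    label: str = "contacts",
) -> ScalarSeries:
    values = np.array([
        contact_count(traj[i], topology, sel_a, sel_b, criteria)
        for i in range(traj.n_frames)
    ], dtype=float)
    return ScalarSeries(values, dt=traj.dt, t0=traj.t0, label=label)


def saltbridge_occupancy(
    series: ScalarSeries,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> float:
    """Fraction of frames with the pair distance strictly below the cutoff.

    Applied to a minimum side-chain heavy-atom distance series, this is
    the salt-bridge occupancy (e.g. "the distance remains < 3.5 Å in
    ~40% of sampled conformations").
    """
    if series.n_frames == 0:
        raise ValueError("cannot compute occupancy of an empty series")
    return float(np.mean(series.values < criteria.saltbridge_cut))


def xbond_distance_series(
    traj: FrameSeries,
    halogen_index: int,
    acceptor_index: int,
    label: str = "xbond_length",
) -> ScalarSeries:
    """Raw X···A distance per frame, tracked independently of any cutoff."""
    d = np.linalg.norm(
        traj.coordinates[:, halogen_index, :]
        - traj.coordinates[:, acceptor_index, :],
        axis=1,
    )
    return ScalarSeries(d, dt=traj.dt, t0=traj.t0, label=label)
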