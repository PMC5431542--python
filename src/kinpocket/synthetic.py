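"""Synthetic trajectories with planted, machine-readable ground truth.

Real kinase–inhibitor trajectories come from hundred-nanosecond MD runs
that cannot be regenerated on demand, so every analysis stage in this
package is validated against a synthetic scene whose statistical and
geometric structure is known exactly:

* a two-state side-chain pair (a toy R858–E758 salt bridge) whose
  minimum side-chain distance switches between a bound and an unbound
  value via a two-state Markov chain with a chosen stationary bound
  fraction;
* a "breathing" helix group whose centre of mass oscillates at planted
  per-frame distances from a static hinge group (the pocket-size
  metric's ground truth);
* a hydration site between a ligand fluorine and a carboxylate, occupied
  by exchanging water molecules according to an explicit schedule, with
  hydrogen- and halogen-bond geometry satisfied by construction while
  occupied;
* an isotropic-Gaussian probe atom for the RMSF closed form (RMSF → σ√3);
* an optional global rigid-body motion over all atoms, which every
  distance metric must be invariant to and superposition must remove.

The default parameters mirror the study conditions the analyses target:
10,000 frames at 10 ps (100 ns), a 40% bound salt bridge at 2.9 Å versus
a ~12 Å separated state, a ~20.5 Å pocket, and a hydration site occupied
for 50 ns through 4 water-exchange events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import Atom, AtomSelection, FrameSeries, Topology, write_frames

__all__ = [
    "TwoStatePair",
    "PocketBreathing",
    "ThermalNoise",
    "RigidBody",
    "HydrationSite",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "write_fixture",
    "load_truth",
]

_SCHEMA_VERSION = 1


@dataclass
class TwoStatePair:
    """Two-state side-chain distance dynamics (bound/unbound Markov chain).

    ``switching_rate`` scales the per-frame transition probabilities:
    P(bound→unbound) = rate·(1−p_bound), P(unbound→bound) = rate·p_bound,
    which leaves the stationary bound probability exactly ``p_bound`` for
    any rate in (0, 1].  rate = 1 gives an iid state sequence.
    """

    bound_dist: float = 2.9
    unbound_dist: float = 12.0
    p_bound: float = 0.4
    switching_rate: float = 0.5

    def validate(self):
        if not 0.0 <= self.p_bound <= 1.0:
            raise ValueError("p_bound must lie in [0, 1]")
        if not 0.0 < self.switching_rate <= 1.0:
            raise ValueError("switching_rate must lie in (0, 1]")
        if self.bound_dist <= 0 or self.unbound_dist <= 0:
            raise ValueError("distances must be positive")


@dataclass
class PocketBreathing:
    """Sinusoidal helix-COM–hinge-COM distance: mean + amplitude·sin(2πi/period)."""

    mean: float = 20.5
    amplitude: float = 0.8
    period: int = 500

    def validate(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.mean - self.amplitude <= 0:
            raise ValueError("pocket distance must stay positive")
        if self.period < 1:
            raise ValueError("period must be >= 1 frame")


@dataclass
class ThermalNoise:
    """iid per-atom, per-frame Gaussian jitter on the probe residue."""

    sigma: float = 0.5

    def validate(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class RigidBody:
    """Global per-frame rigid motion of the whole system."""

    amplitude: float = 1.0  # Å, translation drawn uniformly per axis
    rotation_amplitude: float = 5.0  # degrees, rotation angle upper bound

    def validate(self):
        if self.amplitude < 0 or self.rotation_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")


# Default occupancy: half the trajectory through 4 water-exchange events
# (fractions of n_frames; at 10,000 frames x 10 ps this is 50 ns occupied).
_DEFAULT_SCHEDULE_FRACTIONS = [
    (0.00, 0.10, 1001),
    (0.10, 0.20, 1002),
    (0.20, 0.25, 1003),
    (0.60, 0.70, 1004),
    (0.70, 0.80, 1002),
    (0.80, 0.85, 1005),
]


@dataclass
class HydrationSite:
    """Scheduled occupancy of the ligand-F/carboxylate hydration site.

    Each schedule entry ``(start_frame, end_frame, water_id)`` places the
    named water's oxygen at the site for frames [start, end); while
    occupied, the geometry satisfies the default hydrogen-bond criterion
    toward the protein carboxylate (O···O 2.8 Å, angle 180°) and the
    halogen-bond criterion from the ligand fluorine (F···O 3.0 Å, C–F···O
    180°).  Off-schedule waters are parked ≥ 10 Å from both anchors.

    ``schedule=None`` (the default) uses a built-in schedule that scales
    with the trajectory length: the site is occupied for half the frames
    through four water-exchange events.
    """

    schedule: list[tuple[int, int, int]] | None = None
    n_idle_waters: int = 1

    def resolved_schedule(self, n_frames: int) -> list[tuple[int, int, int]]:
        if self.schedule is not None:
            return sorted(self.schedule)
        sched = []
        for f0, f1, wid in _DEFAULT_SCHEDULE_FRACTIONS:
            start, end = round(f0 * n_frames), round(f1 * n_frames)
            if end > start:
                sched.append((start, end, wid))
        return sched

    def validate(self, n_frames: int):
        prev_end = None
        for start, end, water_id in self.resolved_schedule(n_frames):
            if not (0 <= start < end <= n_frames):
                raise ValueError(
                    f"schedule entry ({start},{end},{water_id}) outside "
                    f"[0, {n_frames})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    "overlapping hydration schedule entries would demand "
                    "contradictory geometry"
                )
            prev_end = end
        if self.n_idle_waters < 0:
            raise ValueError("n_idle_waters must be >= 0")

    def water_ids(self, n_frames: int) -> list[int]:
        return sorted({w for _, _, w in self.resolved_schedule(n_frames)})


@dataclass
class SyntheticSpec:
    """Full description of a synthetic scene; deterministic given the seed."""

    n_frames: int = 10_000
    dt: float = 10.0  # ps per frame
    seed: int = 0
    two_state: TwoStatePair | None = field(default_factory=TwoStatePair)
    breathing: PocketBreathing | None = field(default_factory=PocketBreathing)
    noise: ThermalNoise | None = field(default_factory=ThermalNoise)
    rigid: RigidBody | None = field(default_factory=RigidBody)
    hydration: HydrationSite | None = field(default_factory=HydrationSite)

    def validate(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        for comp in (self.two_state, self.breathing, self.noise, self.rigid):
            if comp is not None:
                comp.validate()
        if self.hydration is not None:
            self.hydration.validate(self.n_frames)

    def to_dict(self) -> dict:
        d = {"n_frames": self.n_frames, "dt": self.dt, "seed": self.seed}
        for name in ("two_state", "breathing", "noise", "rigid", "hydration"):
            comp = getattr(self, name)
            d[name] = asdict(comp) if comp is not None else None
        if d["hydration"] is not None and d["hydration"]["schedule"] is not None:
            d["hydration"]["schedule"] = [list(e) for e in d["hydration"]["schedule"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        kwargs = {k: d[k] for k in ("n_frames", "dt", "seed") if k in d}
        types = {
            "two_state": TwoStatePair, "breathing": PocketBreathing,
            "noise": ThermalNoise, "rigid": RigidBody,
            "hydration": HydrationSite,
        }
        for name, typ in types.items():
            if name in d:
                val = d[name]
                if val is None:
                    kwargs[name] = None
                else:
                    val = dict(val)
                    if name == "hydration" and val.get("schedule") is not None:
                        val["schedule"] = [tuple(e) for e in val["schedule"]]
                    kwargs[name] = typ(**val)
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Every planted quantity, sufficient to score the pipeline's outputs."""

    dt: float
    n_frames: int
    # pocket breathing
    pocket_distances: np.ndarray | None = None
    # two-state salt bridge
    saltbridge_distances: np.ndarray | None = None
    saltbridge_bound: np.ndarray | None = None
    p_bound: float | None = None
    realized_bound_fraction: float | None = None
    # hydration
    occupancy_schedule: list[tuple[int, int, int]] | None = None
    occupied: np.ndarray | None = None
    total_residence_ps: float | None = None
    longest_interval_ps: float | None = None
    n_exchange_events: int | None = None
    # thermal noise probe
    rmsf_sigma: float | None = None
    probe_atom_names: list[str] | None = None
    # contacts (ligand heavy vs helix heavy, planted geometry)
    contact_counts: np.ndarray | None = None
    mean_contacts: float | None = None

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        d = {k: conv(v) for k, v in asdict(self).items()}
        if d.get("occupancy_schedule") is not None:
            d["occupancy_schedule"] = [list(e) for e in d["occupancy_schedule"]]
        d["schema_version"] = _SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        version = d.pop("schema_version", _SCHEMA_VERSION)
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported truth schema version {version}")
        arrays = {
            "pocket_distances": float, "saltbridge_distances": float,
            "saltbridge_bound": bool, "occupied": bool,
            "contact_counts": int,
        }
        for key, typ in arrays.items():
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=typ)
        if d.get("occupancy_schedule") is not None:
            d["occupancy_schedule"] = [tuple(e) for e in d["occupancy_schedule"]]
        return cls(**d)


# --- scene construction -----------------------------------------------------

def _residue(chain: str, res_id: int, res_name: str,
             atoms: list[tuple[str, str, tuple[float, float, float]]]):
    """(Atom list, coordinate list) for one residue template."""
    from .io import Atom as _A
    import biotite.structure.info as info

    atom_objs, coords = [], []
    for name, element, xyz in atoms:
        atom_objs.append(_A(name=name, element=element,
                            mass=float(info.mass(element)),
                            res_name=res_name, res_id=res_id, chain_id=chain))
        coords.append(xyz)
    return atom_objs, coords


_ALA_TEMPLATE = [
    ("N", "N", (0.0, 1.2, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.3, -0.6, 0.0)),
    ("O", "O", (1.4, -1.8, 0.3)),
    ("CB", "C", (-1.1, -0.6, 0.9)),
]


def _ala(chain: str, res_id: int, center: np.ndarray):
    atoms = [(n, e, tuple(np.asarray(x) + center)) for n, e, x in _ALA_TEMPLATE]
    return _residue(chain, res_id, "ALA", atoms)


def _glu(chain: str, res_id: int, oe1: np.ndarray):
    """GLU with OE1 at the given point; side chain extends toward −x."""
    oe1 = np.asarray(oe1, dtype=float)
    offsets = [
        ("OE1", "O", (0.0, 0.0, 0.0)),
        ("OE2", "O", (-0.5, 1.1, 0.0)),
        ("CD", "C", (-0.8, -0.9, 0.2)),
        ("CG", "C", (-2.2, -1.1, 0.0)),
        ("CB", "C", (-3.0, -2.2, 0.4)),
        ("CA", "C", (-4.4, -2.1, 0.0)),
        ("N", "N", (-5.1, -1.0, 0.4)),
        ("C", "C", (-5.0, -3.4, 0.3)),
        ("O", "O", (-4.5, -4.4, -0.2)),
    ]
    atoms = [(n, e, tuple(oe1 + np.asarray(x))) for n, e, x in offsets]
    return _residue(chain, res_id, "GLU", atoms)


# ARG side chain laid out along +x from NH1; all other atoms sit at larger
# +x offsets so the NH1–OE1 distance is exactly the planted minimum.
_ARG_OFFSETS = [
    ("NH1", "N", (0.0, 0.0, 0.0)),
    ("CZ", "C", (1.33, 0.2, 0.0)),
    ("NH2", "N", (1.9, 1.4, 0.1)),
    ("NE", "N", (2.2, -0.9, -0.1)),
    ("CD", "C", (3.5, -0.5, 0.3)),
    ("CG", "C", (4.6, -1.4, -0.1)),
    ("CB", "C", (5.9, -0.9, 0.4)),
    ("CA", "C", (7.0, -1.8, 0.0)),
    ("N", "N", (7.2, -3.0, 0.6)),
    ("C", "C", (8.3, -1.1, 0.2)),
    ("O", "O", (9.3, -1.7, -0.2)),
]


def _arg(chain: str, res_id: int, nh1: np.ndarray):
    atoms = [(n, e, tuple(np.asarray(nh1) + np.asarray(x)))
             for n, e, x in _ARG_OFFSETS]
    return _residue(chain, res_id, "ARG", atoms)


_LIG_ATOMS = [
    ("C1", "C", (16.0, 0.0, 0.0)),
    ("F1", "F", (16.0, 1.35, 0.0)),
    ("N1", "N", (15.0, -0.8, 0.0)),
    ("H11", "H", (14.6, -1.6, 0.6)),
    ("O1", "O", (17.2, -0.7, 0.0)),
    ("C2", "C", (14.9, 0.5, 1.2)),
    ("C3", "C", (16.8, -0.9, -0.9)),
    ("C4", "C", (14.8, 0.2, -1.0)),
]

_SITE_O = np.array([16.0, 4.35, 0.0])  # F1 + 3.0 Å along the C1→F1 axis
_E762_OE1 = _SITE_O + np.array([0.0, 0.0, 2.8])  # water-O···OE1 = 2.8 Å
_E758_OE1 = np.array([18.0, 6.0, -8.0])
_PARK_ORIGIN = np.array([50.0, 50.0, 50.0])
_WATER_H1 = np.array([0.0, 0.0, 0.96])  # toward OE1: linear O-H···O
_WATER_H2 = np.array([0.90, 0.0, -0.30])


class _Scene:
    """Static topology plus bookkeeping of the special atom groups."""

    def __init__(self, n_waters: int, water_ids: list[int]):
        atoms: list[Atom] = []
        coords: list = []
        self.groups: dict[str, list[int]] = {}

        def add(label, residue):
            res_atoms, res_coords = residue
            start = len(atoms)
            atoms.extend(res_atoms)
            coords.extend(res_coords)
            self.groups.setdefault(label, []).extend(
                range(start, start + len(res_atoms))
            )

        # Hinge (static) near the origin.
        for i, center in enumerate([(0.0, 0.0, 0.0), (2.0, 0.0, 1.5),
                                    (4.0, 0.0, 0.0)]):
            add("hinge", _ala("A", 790 + i, np.asarray(center)))
        # Helix (breathing) — base placement; repositioned per frame.
        for i, center in enumerate([(20.5, 0.0, 0.0), (22.5, 0.0, 1.5),
                                    (24.5, 0.0, 0.0)]):
            add("helix", _ala("A", 759 + i, np.asarray(center)))
        # Salt-bridge glutamate (static) and arginine (moved per frame).
        add("glu758", _glu("A", 758, _E758_OE1))
        add("arg858", _arg("A", 858, _E758_OE1 + np.array([12.0, 0.0, 0.0])))
        # Hydration protein anchor.
        add("glu762", _glu("A", 762, _E762_OE1))
        # Ligand.
        add("ligand", _residue("L", 1, "LIG", _LIG_ATOMS))
        # Thermal-noise probe.
        add("probe", _residue("P", 999, "PRB",
                              [("CP1", "C", (30.0, 30.0, 30.0))]))
        # Waters: scheduled ids first, then idle ones.
        all_ids = list(water_ids)
        next_id = (max(water_ids) + 1) if water_ids else 1001
        while len(all_ids) < n_waters:
            all_ids.append(next_id)
            next_id += 1
        self.water_ids = all_ids
        self.water_atom_indices: dict[int, list[int]] = {}
        for k, wid in enumerate(all_ids):
            park = _PARK_ORIGIN + 5.0 * np.array([k % 4, (k // 4) % 4, k // 16])
            res = _residue("W", wid, "HOH", [
                ("O", "O", tuple(park)),
                ("H1", "H", tuple(park + _WATER_H1)),
                ("H2", "H", tuple(park + _WATER_H2)),
            ])
            start = len(atoms)
            add("water", res)
            self.water_atom_indices[wid] = list(range(start, start + 3))
            self.park_positions = getattr(self, "park_positions", {})
            self.park_positions[wid] = park

        self.topology = Topology(atoms)
        self.base_coords = np.asarray(coords, dtype=np.float64)


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _schedule_arrays(schedule, n_frames):
    """Per-frame occupying water id (-1 = empty) and occupancy bool."""
    occupant = np.full(n_frames, -1, dtype=int)
    for start, end, wid in schedule:
        occupant[start:end] = wid
    return occupant, occupant >= 0


def _schedule_truth(schedule, occupant, occupied, dt):
    total = float(occupied.sum()) * dt
    # longest contiguous occupied run
    longest = run = 0
    for o in occupied:
        run = run + 1 if o else 0
        longest = max(longest, run)
    exchanges = int(np.sum(
        occupied[1:] & occupied[:-1] & (occupant[1:] != occupant[:-1])
    ))
    return total, float(longest) * dt, exchanges


def generate(spec: SyntheticSpec) -> tuple[Topology, FrameSeries, GroundTruth]:
    """Generate the scene: deterministic for a given spec (seed included)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    water_ids = spec.hydration.water_ids(n) if spec.hydration else []
    n_waters = len(water_ids) + (spec.hydration.n_idle_waters
                                 if spec.hydration else 2)
    scene = _Scene(n_waters=max(n_waters, 1), water_ids=water_ids)
    top = scene.topology
    coords = np.broadcast_to(scene.base_coords, (n,) + scene.base_coords.shape).copy()
    truth = GroundTruth(dt=spec.dt, n_frames=n)

    helix_idx = np.array(scene.groups["helix"])
    hinge_idx = np.array(scene.groups["hinge"])
    masses = top.masses

    # Pocket breathing: helix COM placed at planted distance from hinge COM.
    if spec.breathing is not None:
        b = spec.breathing
        d = b.mean + b.amplitude * np.sin(2 * np.pi * np.arange(n) / b.period)
        com_hinge = np.average(scene.base_coords[hinge_idx], axis=0,
                               weights=masses[hinge_idx])
        com_helix = np.average(scene.base_coords[helix_idx], axis=0,
                               weights=masses[helix_idx])
        rel = scene.base_coords[helix_idx] - com_helix
        target = com_hinge[None, :] + d[:, None] * np.array([1.0, 0.0, 0.0])
        coords[:, helix_idx, :] = rel[None, :, :] + target[:, None, :]
        truth.pocket_distances = d

    # Two-state salt bridge: ARG side chain placed at planted min distance.
    if spec.two_state is not None:
        ts = spec.two_state
        a = ts.switching_rate * (1.0 - ts.p_bound)  # P(bound -> unbound)
        bpr = ts.switching_rate * ts.p_bound        # P(unbound -> bound)
        states = np.empty(n, dtype=bool)
        states[0] = rng.random() < ts.p_bound
        u = rng.random(n)
        for i in range(1, n):
            if states[i - 1]:
                states[i] = u[i] >= a
            else:
                states[i] = u[i] < bpr
        dists = np.where(states, ts.bound_dist, ts.unbound_dist)
        arg_idx = np.array(scene.groups["arg858"])
        offsets = np.array([o for _, _, o in _ARG_OFFSETS])
        nh1 = _E758_OE1[None, :] + dists[:, None] * np.array([1.0, 0.0, 0.0])
        coords[:, arg_idx, :] = nh1[:, None, :] + offsets[None, :, :]
        truth.saltbridge_distances = dists.astype(float)
        truth.saltbridge_bound = states
        truth.p_bound = ts.p_bound
        truth.realized_bound_fraction = float(states.mean())

    # Hydration schedule: occupying water at the site, others parked.
    if spec.hydration is not None:
        schedule = spec.hydration.resolved_schedule(n)
        occupant, occupied = _schedule_arrays(schedule, n)
        site_pos = np.array([_SITE_O, _SITE_O + _WATER_H1, _SITE_O + _WATER_H2])
        for wid in scene.water_ids:
            widx = scene.water_atom_indices[wid]
            frames_here = np.flatnonzero(occupant == wid)
            if len(frames_here):
                coords[np.ix_(frames_here, widx)] = site_pos[None, :, :]
        total, longest, exchanges = _schedule_truth(
            schedule, occupant, occupied, spec.dt
        )
        truth.occupancy_schedule = schedule
        truth.occupied = occupied
        truth.total_residence_ps = total
        truth.longest_interval_ps = longest
        truth.n_exchange_events = exchanges

    # Contact ground truth from planted (pre-noise, pre-rigid) geometry.
    lig_idx = np.array(scene.groups["ligand"])
    lig_heavy = lig_idx[top.elements[lig_idx] != "H"]
    diff = coords[:, lig_heavy, None, :] - coords[:, None, helix_idx, :]
    dmat = np.linalg.norm(diff, axis=-1)
    counts = (dmat <= 6.5).sum(axis=(1, 2))
    truth.contact_counts = counts.astype(int)
    truth.mean_contacts = float(counts.mean())

    # Thermal noise on the probe residue.
    if spec.noise is not None and spec.noise.sigma > 0:
        probe_idx = np.array(scene.groups["probe"])
        coords[:, probe_idx, :] += rng.normal(
            0.0, spec.noise.sigma, size=(n, len(probe_idx), 3)
        )
        truth.rmsf_sigma = spec.noise.sigma
        truth.probe_atom_names = [top.atom_names[i] for i in probe_idx]

    # Global rigid-body motion, applied last; all metrics must shrug it off.
    if spec.rigid is not None and (
        spec.rigid.amplitude > 0 or spec.rigid.rotation_amplitude > 0
    ):
        for i in range(n):
            rot = _random_rotation(rng, spec.rigid.rotation_amplitude)
            trans = rng.uniform(-spec.rigid.amplitude, spec.rigid.amplitude, 3)
            coords[i] = coords[i] @ rot.T + trans

    frames = FrameSeries(coords, dt=spec.dt)
    return top, frames, truth


def write_fixture(
    topology: Topology,
    frames: FrameSeries,
    truth: GroundTruth,
    out_dir,
    spec: SyntheticSpec | None = None,
) -> dict[str, Path]:
    """Write scene.pdb (multi-model), truth.json and optionally spec.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"trajectory": out_dir / "scene.pdb", "truth": out_dir / "truth.json"}
    try:
        write_frames(topology, frames, paths["trajectory"])
        with open(paths["truth"], "w") as fh:
            json.dump(truth.to_dict(), fh)
        if spec is not None:
            import yaml

            paths["spec"] = out_dir / "spec.yaml"
            with open(paths["spec"], "w") as fh:
                yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out_dir}: {exc}") from exc
    return paths


def load_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(json.load(fh))


def scene_analysis_config(topology_path, trajectory_path, dt: float = 10.0,
                          out_dir="out") -> dict:
    """Analysis-config dict matching the synthetic scene's residue layout.

    Selections name the scene's toy αC-helix (ALA 759-761), hinge
    (ALA 790-792), the R858/E758 salt-bridge pair, the fluorinated
    ligand, and the ligand-F/E762-carboxylate hydration site.
    """
    return {
        "topology": str(topology_path),
        "trajectory": str(trajectory_path),
        "dt": dt,
        "out_dir": str(out_dir),
        "bin_width": 0.1,
        "selections": {
            "helix": "resid 759:761",
            "hinge": "resid 790:792",
            "ligand": "resname LIG",
            "ligand_halogens": "resname LIG and element F",
            "waters": "water and name O",
        },
        "metrics": {
            "pocket": {"helix": "helix", "hinge": "hinge"},
            "saltbridge": [{
                "label": "R858-E758",
                "group_a": "resid 858 and sidechain and heavy",
                "group_b": "resid 758 and sidechain and heavy",
            }],
            "contacts": [{
                "label": "ligand_helix",
                "group_a": "ligand",
                "group_b": "helix",
            }],
            "xbonds": [{
                "label": "ligand_water",
                "halogens": "ligand_halogens",
                "acceptors": "waters",
            }],
            "rmsd": {"fit": "resid 790:792 and heavy"},
            "rmsf": {"fit": "resid 790:792 and heavy",
                     "measure": "resname PRB"},
            "hydration": [{
                "label": "F_site",
                "ligand_anchor": "resname LIG and name F1",
                "protein_anchor": "resid 762 and name OE1 OE2",
                "waters": "waters",
            }],
        },
    }
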