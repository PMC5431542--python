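"""Geometric kernels for trajectory analysis.

Centres of mass, minimum group distances, Kabsch least-squares
superposition, RMSD/RMSF, the binding-pocket size series (αC-helix COM to
hinge COM) and normalised probability distributions of scalar series.
All distances in Å, times in ps.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import AtomSelection, FrameSeries, Topology

__all__ = [
    "ScalarSeries",
    "Distribution",
    "RmsfProfile",
    "center_of_mass",
    "min_group_distance",
    "pocket_size_series",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "distribution",
]


@dataclass
class ScalarSeries:
    """A per-frame scalar observable (a distance, a count, ...)."""

    values: np.ndarray
    dt: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("ScalarSeries values must be one-dimensional")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_frames)

    def to_csv(self, path_or_buf, header_lines: tuple[str, ...] = ()) -> None:
        """Write ``frame_index,time_ps,value`` rows at 6 significant digits."""
        close = False
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            fh = open(path_or_buf, "w")
            close = True
        else:
            fh = path_or_buf
        try:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("frame_index,time_ps,value\n")
            for i, (t, v) in enumerate(zip(self.times, self.values)):
                fh.write(f"{i},{t:.6g},{v:.6g}\n")
        finally:
            if close:
                fh.close()


@dataclass
class Distribution:
    """A normalised histogram: probabilities sum to 1."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ValueError("need len(probabilities) == len(bin_edges) - 1")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def fraction_below(self, threshold: float) -> float:
        """Probability mass strictly below ``threshold``.

        Exact when the threshold coincides with a bin edge (bins are
        left-closed/right-open); otherwise the containing bin contributes
        proportionally under a uniform-within-bin assumption.
        """
        edges, probs = self.bin_edges, self.probabilities
        if threshold <= edges[0]:
            return 0.0
        if threshold >= edges[-1]:
            return 1.0
        total = 0.0
        for left, right, p in zip(edges[:-1], edges[1:], probs):
            if right <= threshold:
                total += p
            elif left < threshold:
                total += p * (threshold - left) / (right - left)
        return float(total)

    def to_csv(self, path_or_buf, header_lines: tuple[str, ...] = ()) -> None:
        close = False
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            fh = open(path_or_buf, "w")
            close = True
        else:
            fh = path_or_buf
        try:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("bin_left,bin_right,probability\n")
            for left, right, p in zip(
                self.bin_edges[:-1], self.bin_edges[1:], self.probabilities
            ):
                fh.write(f"{left:.6g},{right:.6g},{p:.6g}\n")
        finally:
            if close:
                fh.close()


@dataclass
class RmsfProfile:
    """Per-atom root-mean-square fluctuation about the mean aligned position."""

    atom_indices: np.ndarray
    values: np.ndarray  # Å, one per atom of the measured selection
    reference: str = "frames aligned to frame 0; deviations from mean structure"

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.atom_indices) != len(self.values):
            raise ValueError("atom_indices and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("RMSF values cannot be negative")

    def mean(self) -> float:
        return float(self.values.mean())


def _require_nonempty(sel: AtomSelection) -> None:
    if sel.is_empty:
        raise ValueError(f"selection '{sel.label}' is empty")


def center_of_mass(
    coords: np.ndarray, selection: AtomSelection, masses: np.ndarray
) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms, in Å.

    ``coords`` may be a single frame (n_atoms, 3) or a whole trajectory
    (n_frames, n_atoms, 3); the COM is returned per frame in the latter
    case.
    """
    _require_nonempty(selection)
    m = np.asarray(masses, dtype=np.float64)[selection.indices]
    if np.any(m <= 0):
        raise ValueError("masses must be strictly positive")
    xyz = np.asarray(coords, dtype=np.float64)[..., selection.indices, :]
    return np.einsum("...ij,i->...j", xyz, m) / m.sum()


def min_group_distance(
    coords: np.ndarray, sel_a: AtomSelection, sel_b: AtomSelection
) -> float:
    """Minimum Euclidean distance over all cross pairs of two atom groups.

    This is the convention for side-chain pair distances such as the
    R858–E758 salt bridge: the closest approach of any heavy side-chain
    atom pair.  The selections must be disjoint (a shared atom would give
    a degenerate zero).
    """
    _require_nonempty(sel_a)
    _require_nonempty(sel_b)
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise ValueError(
            f"selections '{sel_a.label}' and '{sel_b.label}' overlap"
        )
    xyz = np.asarray(coords, dtype=np.float64)
    return float(cdist(xyz[sel_a.indices], xyz[sel_b.indices]).min())


def min_group_distance_series(
    traj: FrameSeries, sel_a: AtomSelection, sel_b: AtomSelection, label: str = ""
) -> ScalarSeries:
    """Per-frame :func:`min_group_distance`."""
    values = np.array(
        [min_group_distance(traj[i], sel_a, sel_b) for i in range(traj.n_frames)]
    )
    return ScalarSeries(values, dt=traj.dt, t0=traj.t0,
                        label=label or f"min({sel_a.label},{sel_b.label})")


def pocket_size_series(
    traj: FrameSeries,
    helix_sel: AtomSelection,
    hinge_sel: AtomSelection,
    masses: np.ndarray,
    label: str = "pocket_size",
) -> ScalarSeries:
    """Binding-pocket size: per-frame |COM(helix) − COM(hinge)| in Å.

    The distance between the αC-helix centre of mass and the hinge-region
    centre of mass tracks compaction of the ATP/inhibitor pocket.
    """
    com_helix = center_of_mass(traj.coordinates, helix_sel, masses)
    com_hinge = center_of_mass(traj.coordinates, hinge_sel, masses)
    values = np.linalg.norm(com_helix - com_hinge, axis=-1)
    return ScalarSeries(values, dt=traj.dt, t0=traj.t0, label=label)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_sel: AtomSelection,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD over
    ``fit_sel``.  The rotation is proper (det = +1); reflections are
    corrected by sign-flipping the smallest singular direction.

    Raises if the fit selection has fewer than three atoms or is
    collinear (the rotation would be under-determined).
    """
    _require_nonempty(fit_sel)
    idx = fit_sel.indices
    if len(idx) < 3:
        raise ValueError(
            f"superposition needs >= 3 fit atoms, got {len(idx)}"
        )
    mob = np.asarray(mobile, dtype=np.float64)[idx]
    ref = np.asarray(reference, dtype=np.float64)[idx]
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    p = mob - mob_c
    q = ref - ref_c
    # Collinearity check on the reference fit atoms.
    sv = np.linalg.svd(q, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise ValueError("fit atoms are collinear; rotation under-determined")
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    fitted = p @ rotation.T + ref_c
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def _apply_transform(coords: np.ndarray, rotation: np.ndarray,
                     translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def rmsd_series(
    traj: FrameSeries,
    fit_sel: AtomSelection,
    measure_sel: AtomSelection | None = None,
    label: str = "rmsd",
) -> ScalarSeries:
    """RMSD of each frame against the starting structure (frame 0).

    Each frame is superposed on frame 0 over ``fit_sel``; the RMSD is then
    measured over ``measure_sel`` (defaults to the fit selection).
    """
    if measure_sel is None:
        measure_sel = fit_sel
    _require_nonempty(measure_sel)
    ref = traj[0]
    midx = measure_sel.indices
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj[i], ref, fit_sel)
        fitted = _apply_transform(traj[i][midx], rot, trans)
        values[i] = np.sqrt(np.mean(np.sum((fitted - ref[midx]) ** 2, axis=1)))
    return ScalarSeries(values, dt=traj.dt, t0=traj.t0, label=label)


def rmsf(
    traj: FrameSeries,
    fit_sel: AtomSelection,
    measure_sel: AtomSelection | None = None,
) -> RmsfProfile:
    """Per-atom RMSF after aligning every frame to frame 0 over ``fit_sel``.

    RMSF_i = sqrt( mean_t | x_i(t) − <x_i> |² ) with <x_i> the atom's mean
    aligned position.  Requires at least two frames.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    if measure_sel is None:
        measure_sel = fit_sel
    _require_nonempty(measure_sel)
    midx = measure_sel.indices
    ref = traj[0]
    aligned = np.empty((traj.n_frames, len(midx), 3))
    for i in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj[i], ref, fit_sel)
        aligned[i] = _apply_transform(traj[i][midx], rot, trans)
    mean_pos = aligned.mean(axis=0)
    dev2 = np.sum((aligned - mean_pos) ** 2, axis=2)
    return RmsfProfile(atom_indices=midx, values=np.sqrt(dev2.mean(axis=0)))


def distribution(series: ScalarSeries, bin_width: float = 0.1) -> Distribution:
    """Normalised histogram of a scalar series.

    Bins are left-closed/right-open with edges at integer multiples of
    ``bin_width``, covering [min, max]; a value equal to the last edge
    gets its own bin, so the sum of bins left of an aligned threshold
    equals the exact fraction of values strictly below it.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    v = series.values
    if len(v) == 0:
        raise ValueError("cannot histogram an empty series")
    start = np.floor(v.min() / bin_width) * bin_width
    n_bins = int(np.floor((v.max() - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)
    which = np.floor((v - start) / bin_width).astype(int)
    which = np.clip(which, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    return Distribution(bin_edges=edges, probabilities=counts / counts.sum())
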